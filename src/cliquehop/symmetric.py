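"""The vertex-permutation-symmetric 3-parameter network family.

Averaging any clique-storing network over all vertex relabelings yields a
network with a uniform threshold z and only two distinct off-diagonal weights:
x between edge pairs sharing one vertex and y between disjoint pairs.  This
module builds such networks, evaluates their energy and restricted
probability flow in closed form, provides the analytic flow minimizer and the
large-deviation robust setting, certifies r-stable clique storage via a
4x2 system of strict linear inequalities, and checks feasibility of storing a
whole range of clique sizes.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import linprog
from scipy.stats import norm

from . import codec
from .core import (
    BinaryState,
    ConvergenceError,
    DynamicsResult,
    HopfieldNetwork,
    as_state,
    converge_batch,
)

__all__ = [
    "SymmetricParams",
    "StabilityCertificate",
    "RangeFeasibility",
    "overlap_matrix",
    "build_network",
    "symmetric_energy",
    "restricted_clique_flow",
    "mpf_optimal_x",
    "large_deviation_x",
    "stability_matrix",
    "stability_certificate",
    "feasible_x_interval",
    "exhaustive_r_stability",
    "range_bounds",
    "range_feasible_lp",
    "range_constants",
    "storable_fraction",
    "symmetric_sweep",
    "symmetric_converge",
]


@dataclass(frozen=True)
class SymmetricParams:
    """Weights (x: one shared vertex, y: disjoint) and uniform threshold z."""

    x: float
    y: float
    z: float
    v: int
    k: int | None = None

    def __post_init__(self):
        if self.v < 4:
            raise ValueError("symmetric family needs v >= 4")

    @property
    def n(self) -> int:
        return codec.edge_count(self.v)

    def scaled(self, c: float) -> "SymmetricParams":
        return SymmetricParams(c * self.x, c * self.y, c * self.z, self.v, self.k)


def overlap_matrix(v: int) -> np.ndarray:
    """n x n int8 matrix of shared-vertex counts |e ∩ f| (diagonal set to -1)."""
    I, J = codec.pair_table(v)
    Ic, Jc = I[:, None], J[:, None]
    share = (
        (Ic == I[None, :]).astype(np.int8)
        + (Ic == J[None, :])
        + (Jc == I[None, :])
        + (Jc == J[None, :])
    )
    np.fill_diagonal(share, -1)
    return share


def build_network(params: SymmetricParams) -> HopfieldNetwork:
    """Dense network: W_ef = x if |e∩f| = 1, y if |e∩f| = 0, zero diagonal."""
    ov = overlap_matrix(params.v)
    W = np.where(ov == 1, params.x, 0.0) + np.where(ov == 0, params.y, 0.0)
    np.fill_diagonal(W, 0.0)
    theta = np.full(codec.edge_count(params.v), params.z, dtype=float)
    return HopfieldNetwork(W, theta)


def symmetric_energy(state: BinaryState, params: SymmetricParams) -> float:
    """Closed-form energy -x*S1 - y*S0 + z*#E via the graph statistics."""
    stats = codec.graph_stats(state, params.v)
    return -params.x * stats.s1 - params.y * stats.s0 + params.z * stats.edge_count


def restricted_clique_flow(k: int, x: float, z: float) -> float:
    """Per-clique flow of the (x, 0, z) network over all k-cliques on 2k-2 vertices.

    Single-bit neighbors of a clique fall into three orbits: delete a clique
    edge (C(k,2) of them), add an edge from the clique to an isolated vertex
    (k(k-2)), or add an edge between two isolated vertices (C(k-2,2)).
    """
    if k < 4:
        raise ValueError("closed form requires k >= 4")
    return (
        math.comb(k, 2) * math.exp((z - 2.0 * (k - 2) * x) / 2.0)
        + k * (k - 2) * math.exp(((k - 1) * x - z) / 2.0)
        + math.comb(k - 2, 2) * math.exp(-z / 2.0)
    )


def mpf_optimal_x(k: int, z: float) -> float:
    """Unique minimizer x = 2z / (3k - 5) of the restricted clique flow."""
    if k < 4:
        raise ValueError("requires k >= 4")
    return 2.0 * z / (3.0 * k - 5.0)


def large_deviation_x(k: int, p: float, z: float) -> float:
    """Robust setting x = z(3+2p) / (4k(1+2p)), the midpoint of the
    asymptotic feasibility window (z/2k, z/(k(1+2p))) for design corruption p."""
    if k < 2:
        raise ValueError("requires k >= 2")
    if not (0.0 <= p < 0.5):
        raise ValueError("design corruption must satisfy 0 <= p < 1/2")
    return z * (3.0 + 2.0 * p) / (4.0 * k * (1.0 + 2.0 * p))


# --- r-stability certificates ------------------------------------------------

_RHS_SIGNS = np.array([-2.0, -2.0, 2.0, 2.0])


def stability_matrix(k: int, r: int) -> np.ndarray:
    """The 4x2 coefficient matrix of the strict inequalities M (x,y)^T < (-2,-2,2,2)^T z."""
    if k <= 3:
        raise ValueError("requires k > 3")
    if not (0 <= r < k):
        raise ValueError("requires 0 <= r < k")
    return np.array(
        [
            [4.0 * (2 - k) + 2 * r, (2 - k) * (k - 3)],
            [4.0 * (2 - k), (2 - k) * (k - 3) - 2 * r],
            [2.0 * (k - 1) + 2 * r, (k - 1) * (k - 2)],
            [2.0 * (k - 1), (k - 1) * (k - 2) - 2 * r],
        ]
    )


@dataclass(frozen=True)
class StabilityCertificate:
    k: int
    r: int
    M: np.ndarray
    satisfied: bool
    slack: np.ndarray  # rhs - lhs; all strictly positive iff satisfied
    marginal: bool  # some |slack| below resolution; do not trust the flag


def stability_certificate(
    k: int, r: int, params: SymmetricParams, marginal_tol: float = 1e-12
) -> StabilityCertificate:
    """Evaluate the four strict inequalities for r-stable storage of all k-cliques."""
    M = stability_matrix(k, r)
    lhs = M @ np.array([params.x, params.y])
    slack = _RHS_SIGNS * params.z - lhs
    marginal = bool(np.any(np.abs(slack) < marginal_tol))
    return StabilityCertificate(k, r, M, bool(np.all(slack > 0)), slack, marginal)


def feasible_x_interval(k: int, r: int, z: float = 1.0) -> dict:
    """Candidate x-intervals for y = 0 storage, from two places in the source
    analysis that disagree in the lower bound.

    "matrix": (z/(2(k-2)-r), z/(k-1+r)), implied by the certificate matrix.
    "text":   (z/(2(k-1)-r), z/(k-1+r)), the displayed interval.
    Exhaustive enumeration (see :func:`exhaustive_r_stability`) is the ground
    truth deciding between them.
    """
    if k <= 3:
        raise ValueError("requires k > 3")
    hi = z / (k - 1 + r)
    lo_matrix = z / (2 * (k - 2) - r) if 2 * (k - 2) - r > 0 else math.inf
    lo_text = z / (2 * (k - 1) - r) if 2 * (k - 1) - r > 0 else math.inf
    return {
        "matrix": (lo_matrix, hi, lo_matrix < hi),
        "text": (lo_text, hi, lo_text < hi),
    }


@dataclass(frozen=True)
class StabilityCheck:
    ok: bool
    states_checked: int
    cliques_checked: int
    counterexample: tuple | None  # (clique_vertices, start_state) or None


def exhaustive_r_stability(
    k: int,
    v: int,
    r: int,
    params: SymmetricParams,
    sample_cap: int = 2_000_000,
    cliques=None,
    seed=None,
    order_policy: str = "ascending",
) -> StabilityCheck:
    """Brute-force check that every state within Hamming distance <= r of a
    k-clique converges back to that clique.

    By default all C(v, k) cliques are enumerated; ``cliques`` may supply an
    explicit (e.g. seeded) list of vertex tuples instead.  If the total number
    of dynamics runs would exceed ``sample_cap`` the call refuses outright
    rather than silently sampling.
    """
    if params.v != v:
        raise ValueError("params.v must equal v")
    n = codec.edge_count(v)
    if cliques is None:
        cliques = list(itertools.combinations(range(v), k))
    ball = sum(math.comb(n, s) for s in range(r + 1))
    if ball * len(cliques) > sample_cap:
        raise ValueError(
            f"{ball * len(cliques)} dynamics runs exceed sample_cap={sample_cap}; "
            "pass an explicit clique sample or raise the cap"
        )
    net = build_network(params)
    flip_sets = [
        np.array(c, dtype=int)
        for s in range(r + 1)
        for c in itertools.combinations(range(n), s)
    ]
    checked = 0
    for verts in cliques:
        base = codec.clique_state(verts, v)
        S = np.tile(base.astype(float), (len(flip_sets), 1))
        for row, flips in enumerate(flip_sets):
            S[row, flips] = 1.0 - S[row, flips]
        starts = S.copy()
        try:
            fixed, _ = converge_batch(S, net, order_policy=order_policy, seed=seed)
        except ConvergenceError:
            fixed = None
        if fixed is None or not np.array_equal(fixed, np.tile(base, (len(flip_sets), 1))):
            bad = (
                0
                if fixed is None
                else int(np.flatnonzero((fixed != base).any(axis=1))[0])
            )
            return StabilityCheck(
                False,
                checked + len(flip_sets),
                0,
                (tuple(verts), starts[bad].astype(np.uint8)),
            )
        checked += len(flip_sets)
    return StabilityCheck(True, checked, len(cliques), None)


# --- clique-range storage ----------------------------------------------------

@dataclass(frozen=True)
class RangeFeasibility:
    m: int
    M_upper: int
    x_m: float
    x_M: float
    feasible: bool  # x_M - x_m < 0


def range_bounds(m: int, M_upper: int) -> RangeFeasibility:
    """Closed-form feasibility of storing all k-cliques for every k in [m, M].

    Works at the normalization z = 1/2, r = 0 (scale invariance makes the
    verdict normalization-free).
    """
    if not (3 <= m <= M_upper):
        raise ValueError("need 3 <= m <= M")

    def _disc(t: int) -> float:
        d = 12.0 * t * t - 52.0 * t + 57.0
        assert d >= 0, "discriminant cannot be negative for t >= 3"
        return math.sqrt(d)

    x_m = -(4.0 * m - _disc(m) - 7.0) / (2.0 * (m * m - m - 2.0))
    x_M = -(4.0 * M_upper + _disc(M_upper) - 7.0) / (2.0 * (M_upper**2 - M_upper - 2.0))
    return RangeFeasibility(m, M_upper, x_m, x_M, x_M - x_m < 0)


def range_feasible_lp(m: int, M_upper: int, margin_tol: float = 1e-9) -> bool:
    """Independent route: maximize the joint slack of the r = 0, z = 1/2
    inequalities over (x, y) for all k in [m, M] with a linear program."""
    if not (3 <= m <= M_upper):
        raise ValueError("need 3 <= m <= M")
    A_ub, b_ub = [], []
    for k in range(m, M_upper + 1):
        # 4(k-2)x + (k-2)(k-3)y - 1 >= t  ->  -4(k-2)x - (k-2)(k-3)y + t <= -1
        A_ub.append([-4.0 * (k - 2), -(k - 2.0) * (k - 3), 1.0])
        b_ub.append(-1.0)
        # 2(k-1)x + (k-1)(k-2)y - 1 <= -t  ->  2(k-1)x + (k-1)(k-2)y + t <= 1
        A_ub.append([2.0 * (k - 1), (k - 1.0) * (k - 2), 1.0])
        b_ub.append(1.0)
    res = linprog(
        c=[0.0, 0.0, -1.0],
        A_ub=A_ub,
        b_ub=b_ub,
        bounds=[(None, None), (None, None), (None, 1.0)],
        method="highs",
    )
    return bool(res.status == 0 and -res.fun > margin_tol)


def range_constants() -> tuple[float, float]:
    """(C, D): D = (2+sqrt(3))/(2-sqrt(3)) and C = (D-1)^2 / (2 D^2)."""
    D = (2.0 + math.sqrt(3.0)) / (2.0 - math.sqrt(3.0))
    C = (D - 1.0) ** 2 / (2.0 * D * D)
    return C, D


def storable_fraction(v: float) -> dict:
    """Asymptotic fraction of all cliques whose size falls in the storable range.

    The missing mass is the normal tail beyond t = ((D-1)/D) sqrt(v); note
    C v = t^2/2 exactly, so 1 - exp(-C v) is the Mill's-ratio style
    approximation of the fraction.  Returns the normal-CDF fraction, its tail
    (kept separately for precision), the exponential approximation, and the
    fraction-vs-approximation gap.
    """
    if v < 1:
        raise ValueError("v must be >= 1")
    C, D = range_constants()
    t = (D - 1.0) / D * math.sqrt(v)
    tail = float(norm.sf(t))
    return {
        "normal": 1.0 - tail,
        "tail": tail,
        "approx": 1.0 - math.exp(-C * v),
        "gap": math.exp(-C * v) - tail,
    }


# --- sparse dynamics (no dense W materialized) --------------------------------

def symmetric_sweep(
    state: BinaryState, params: SymmetricParams, order=None
) -> BinaryState:
    """One asynchronous sweep under (x, y, z) weights using degree bookkeeping.

    The input to edge e = (i, j) is x*(deg(i)+deg(j)-2 x_e) + y*(#E - deg(i)
    - deg(j) + x_e); degrees and the edge count are updated incrementally, so
    no n-by-n matrix is ever formed.  Identical to the dense sweep.
    """
    bits = as_state(state).copy()
    v = params.v
    n = codec.edge_count(v)
    if bits.shape[0] != n:
        raise ValueError(f"state length {bits.shape[0]} does not match v={v}")
    if order is None:
        order = range(n)
    I, J = codec.pair_table(v)
    deg = codec.state_degrees(bits, v)
    m = int(bits.sum())
    x, y, z = params.x, params.y, params.z
    for e in order:
        i, j = int(I[e]), int(J[e])
        b = int(bits[e])
        s1 = deg[i] + deg[j] - 2 * b
        s0 = m - deg[i] - deg[j] + b
        new = 1 if x * s1 + y * s0 > z else 0
        if new != b:
            d = new - b
            bits[e] = new
            deg[i] += d
            deg[j] += d
            m += d
    return bits


def symmetric_converge(
    state: BinaryState,
    params: SymmetricParams,
    order_policy: str = "ascending",
    seed=None,
    max_sweeps: int | None = None,
) -> DynamicsResult:
    """Run the sparse dynamics to a fixed point (semantics of core.converge)."""
    bits = as_state(state)
    n = codec.edge_count(params.v)
    max_sweeps = n if max_sweeps is None else max_sweeps
    rng = np.random.default_rng(seed) if order_policy == "random" else None
    trace = []
    for s in range(1, max_sweeps + 1):
        order = rng.permutation(n) if rng is not None else None
        new = symmetric_sweep(bits, params, order)
        trace.append(symmetric_energy(new, params))
        if np.array_equal(new, bits):
            return DynamicsResult(new, s, tuple(trace))
        bits = new
    raise ConvergenceError(f"no fixed point within {max_sweeps} sweeps")
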