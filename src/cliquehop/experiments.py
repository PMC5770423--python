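"""Seeded experiment drivers: robustness curves, training curves, weight
statistics, hidden-clique denoising, neighbor concentration, and the
robustness-index estimator.

Every driver returns a :class:`TrialTable` — a pandas DataFrame of per-trial
rows plus a metadata dict — and is bit-reproducible from (config, seed).
Dynamics use a seeded random neuron order per sweep unless stated otherwise;
"recovered" always means exact bit equality with the uncorrupted pattern,
with partial credit reported separately as bit accuracy.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import codec, symmetric
from .core import HopfieldNetwork, as_state, converge_batch
from .mpf import fit_mpf
from .symmetric import (
    SymmetricParams,
    build_network,
    large_deviation_x,
    mpf_optimal_x,
    symmetric_converge,
)

__all__ = [
    "TrialTable",
    "NeighborStats",
    "preset_params",
    "robustness_curve",
    "training_curve",
    "weight_group_stats",
    "hidden_clique_solve",
    "is_clique",
    "neighbor_stats",
    "estimate_alpha",
    "corrupt_with_uniforms",
]

#: threshold for switching from dense batched dynamics to the sparse
#: degree-bookkeeping path (n(n-1) weight entries get large quickly)
_DENSE_LIMIT = 3000


@dataclass
class TrialTable:
    table: pd.DataFrame
    meta: dict = field(default_factory=dict)

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    def save_meta(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.meta, fh, indent=2, default=str)


def preset_params(name: str, k: int, v: int, p: float = 0.25) -> SymmetricParams:
    """Named (x, y, z) presets: 'mpf-theory' and 'large-deviation'.

    The 'mpf-fit' preset of the figures is a trained network, not a triple;
    obtain it with :func:`cliquehop.mpf.fit_mpf`.
    """
    if name == "mpf-theory":
        return SymmetricParams(mpf_optimal_x(k, 1.0), 0.0, 1.0, v, k)
    if name == "large-deviation":
        return SymmetricParams(large_deviation_x(k, p, 1.0), 0.0, 1.0, v, k)
    raise ValueError(f"unknown preset {name!r} (try 'mpf-theory' or 'large-deviation')")


def corrupt_with_uniforms(states: np.ndarray, U: np.ndarray, p: float) -> np.ndarray:
    """Flip bits where U < p.  Sharing U across a p-grid couples the
    corruptions (flip sets are nested in p), giving common random numbers."""
    return np.where(U < p, 1 - states, states)


def _converge_rows(S, net_or_params, order_policy, seed):
    """Converge each row; dense batched path or sparse per-row path."""
    if isinstance(net_or_params, HopfieldNetwork):
        fixed, _ = converge_batch(S, net_or_params, order_policy=order_policy, seed=seed)
        return fixed
    params = net_or_params
    rows = []
    for r, row in enumerate(np.asarray(S, dtype=np.uint8)):
        res = symmetric_converge(
            row, params, order_policy=order_policy,
            seed=None if seed is None else seed + r,
        )
        rows.append(res.fixed_point)
    return np.vstack(rows)


def _dynamics_backend(params: SymmetricParams):
    n = codec.edge_count(params.v)
    return build_network(params) if n <= _DENSE_LIMIT else params


def robustness_curve(
    v: int,
    k: int,
    params: SymmetricParams,
    p_grid,
    n_patterns: int = 100,
    trials: int = 1,
    seed: int = 0,
    order_policy: str = "random",
) -> TrialTable:
    """Exact-recovery fraction and bit accuracy of p-corrupted cliques.

    Within a trial the same cliques and the same per-bit uniforms are reused
    across the whole p grid (common random numbers), so recovery is coupled
    monotonically in p.
    """
    n = codec.edge_count(v)
    backend = _dynamics_backend(params)
    rng = np.random.default_rng(seed)
    rows = []
    for t in range(trials):
        cliques = codec.random_cliques(v, k, n_patterns, rng=rng)
        C = np.vstack(cliques).astype(np.uint8)
        U = rng.random((n_patterns, n))
        for p in p_grid:
            if not (0.0 <= p <= 0.5):
                raise ValueError("corruption grid must lie in [0, 1/2]")
            noisy = corrupt_with_uniforms(C, U, p).astype(float)
            fixed = _converge_rows(noisy, backend, order_policy, seed + 7919 * t)
            recovered = (fixed == C).all(axis=1)
            bit_acc = (fixed == C).mean(axis=1)
            for i in range(n_patterns):
                rows.append(
                    dict(p=p, trial=t, pattern=i,
                         recovered=bool(recovered[i]),
                         bit_accuracy=float(bit_acc[i]))
                )
    meta = dict(v=v, k=k, x=params.x, y=params.y, z=params.z, seed=seed,
                n_patterns=n_patterns, trials=trials, order_policy=order_policy,
                p_grid=list(map(float, p_grid)))
    return TrialTable(pd.DataFrame(rows), meta)


def _fixed_point_mask(states: np.ndarray, net: HopfieldNetwork) -> np.ndarray:
    """A state is a fixed point iff no single-neuron update flips a bit,
    which for an unchanged state equals the parallel check (I > theta) == x."""
    S = states.astype(float)
    G = S @ net.W - net.theta
    return ((G > 0) == states.astype(bool)).all(axis=1)


def training_curve(
    v: int,
    k: int,
    sample_sizes,
    test_count: int = 200,
    trials: int = 1,
    seed: int = 0,
    fit_options: dict | None = None,
) -> TrialTable:
    """Fit full (W, theta) networks by MPF on growing clique samples and score
    held-out cliques: fraction fixed and mean correct bits after convergence."""
    fit_options = dict(fit_options or {})
    rng = np.random.default_rng(seed)
    total = codec.count_cliques(v, k)
    rows = []
    for t in range(trials):
        held = np.vstack(codec.random_cliques(v, k, test_count, rng=rng)).astype(np.uint8)
        for size in sample_sizes:
            if size < 1:
                raise ValueError("sample sizes must be >= 1")
            train = codec.random_cliques(v, k, size, rng=rng)
            fit = fit_mpf(train, **fit_options)
            fixed_mask = _fixed_point_mask(held, fit.network)
            converged, _ = converge_batch(
                held.astype(float), fit.network, order_policy="random",
                seed=seed + 104729 * t,
            )
            bit_acc = float((converged == held).mean())
            rows.append(
                dict(sample_size=size, training_fraction=size / total, trial=t,
                     fixed_fraction=float(fixed_mask.mean()),
                     bit_accuracy=bit_acc,
                     optimizer_converged=fit.converged,
                     final_flow=fit.final_flow)
            )
    meta = dict(v=v, k=k, test_count=test_count, trials=trials, seed=seed,
                total_cliques=total, fit_options=fit_options,
                sample_sizes=list(map(int, sample_sizes)))
    return TrialTable(pd.DataFrame(rows), meta)


def weight_group_stats(net: HopfieldNetwork, v: int) -> dict:
    """Summaries of off-diagonal weights grouped by shared-vertex count.

    The network is rescaled so thresholds have mean 1 (dynamics-invariant);
    group means then estimate the empirical (x, y, z) triple.
    """
    n = codec.edge_count(v)
    if net.n != n:
        raise ValueError(f"network size {net.n} does not match v={v}")
    theta_mean = float(net.theta.mean())
    if theta_mean == 0.0:
        raise ValueError("mean threshold is zero; cannot normalize to z = 1")
    scale = 1.0 / theta_mean
    ov = symmetric.overlap_matrix(v)
    iu = np.triu_indices(n, 1)
    w = net.W[iu] * scale
    groups = ov[iu]
    out = {"theta_mean_raw": theta_mean, "z_mean": 1.0,
           "z_std": float(net.theta.std() * abs(scale))}
    for label, flag in (("x", 1), ("y", 0)):
        vals = w[groups == flag]
        mean = float(vals.mean())
        std = float(vals.std())
        out[f"{label}_mean"] = mean
        out[f"{label}_std"] = std
        out[f"{label}_cv"] = std / abs(mean) if mean != 0.0 else np.inf
    out["params"] = SymmetricParams(out["x_mean"], out["y_mean"], 1.0, v)
    return out


def is_clique(state, v: int) -> tuple[bool, int]:
    """(is a clique graph, clique size).  The empty graph counts as size 0."""
    state = as_state(state)
    m = int(state.sum())
    if m == 0:
        return True, 0
    deg = codec.state_degrees(state, v)
    support = int((deg > 0).sum())
    ok = m == support * (support - 1) // 2 and bool(np.all(deg[deg > 0] == support - 1))
    return ok, support if ok else 0


def hidden_clique_solve(
    noisy_state,
    params: SymmetricParams,
    order_policy: str = "ascending",
    seed=None,
) -> tuple[np.ndarray, dict]:
    """Converge the dynamics from a noisy graph; report the fixed point and
    whether it is a clique (non-clique fixed points are reported, not errors)."""
    res = symmetric_converge(
        as_state(noisy_state), params, order_policy=order_policy, seed=seed
    )
    ok, size = is_clique(res.fixed_point, params.v)
    info = dict(is_clique=ok, clique_size=size, sweeps=res.sweeps,
                energy=res.energy_trace[-1])
    return res.fixed_point, info


@dataclass(frozen=True)
class NeighborStats:
    """Degree extrema of a p-corrupted clique (clique on vertices 0..k-1, v = 2k)."""

    M_in: int
    m_in: int
    M_out: int
    m_out: int
    M_between: int

    def __post_init__(self):
        if self.m_in > self.M_in or self.m_out > self.M_out:
            raise ValueError("minima cannot exceed maxima")


def neighbor_stats(k: int, p: float, trials: int, seed: int = 0) -> TrialTable:
    """Simulate the five extremal degree statistics of corrupted cliques.

    i_in counts edges from vertex i to clique vertices, i_out to non-clique
    vertices; M/m are maxima/minima over clique (in) or non-clique (out)
    vertices, and M_between is the largest clique-ward degree of a non-clique
    vertex.  Their centers are k(1-p), k(1-p), kp, kp, kp respectively.
    """
    v = 2 * k
    rng = np.random.default_rng(seed)
    rows = []
    for t in range(trials):
        A = np.zeros((v, v), dtype=np.uint8)
        A[:k, :k] = 1
        np.fill_diagonal(A, 0)
        flips = rng.random((v, v)) < p
        flips = np.triu(flips, 1)
        flips = flips | flips.T
        A = A ^ flips
        in_deg = A[:, :k].sum(axis=1)
        out_deg = A[:, k:].sum(axis=1)
        stats = NeighborStats(
            M_in=int(in_deg[:k].max()), m_in=int(in_deg[:k].min()),
            M_out=int(out_deg[k:].max()), m_out=int(out_deg[k:].min()),
            M_between=int(in_deg[k:].max()),
        )
        rows.append(dict(trial=t, **stats.__dict__))
    meta = dict(k=k, v=v, p=p, trials=trials, seed=seed,
                centers=dict(M_in=k * (1 - p), m_in=k * (1 - p),
                             M_out=k * p, m_out=k * p, M_between=k * p))
    return TrialTable(pd.DataFrame(rows), meta)


def estimate_alpha(
    v: int,
    k: int,
    params: SymmetricParams,
    epsilon: float = 0.1,
    p_step: float = 0.05,
    trials: int = 40,
    seed: int = 0,
    order_policy: str = "random",
) -> float:
    """Largest grid corruption p for which the sampled recovery rate stays at
    least 1 - epsilon: a finite-size estimator of the robustness index
    (which is at most 1/2 by definition)."""
    if not (0.0 < epsilon < 1.0):
        raise ValueError("epsilon must lie in (0, 1)")
    backend = _dynamics_backend(params)
    n = codec.edge_count(v)
    rng = np.random.default_rng(seed)
    cliques = np.vstack(codec.random_cliques(v, k, trials, rng=rng)).astype(np.uint8)
    U = rng.random((trials, n))
    best = 0.0
    p = p_step
    while p <= 0.5 + 1e-12:
        noisy = corrupt_with_uniforms(cliques, U, min(p, 0.5)).astype(float)
        fixed = _converge_rows(noisy, backend, order_policy, seed)
        rate = float((fixed == cliques).all(axis=1).mean())
        if rate < 1.0 - epsilon:
            break
        best = min(p, 0.5)
        p += p_step
    return best
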