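"""Minimum-probability-flow estimation for binary Hopfield networks.

The flow objective for a training set X is

    F(W, theta) = (1/|X|) sum_{x in X} sum_e exp((E_x - E_{x^e}) / 2),

where x^e is x with bit e flipped.  Since flipping bit e changes the energy
by -(1 - 2 x_e)(I_e - theta_e), each term is exp((1-2x_e)(I_e - theta_e)/2)
and the whole objective is computable from the input matrix X W in one pass.
F is convex in (W, theta) and is driven to zero exactly when every training
pattern is a strict energy minimum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

from .core import HopfieldNetwork, as_state

__all__ = [
    "FlowValue",
    "FitResult",
    "probability_flow",
    "probability_flow_gradient",
    "fit_mpf",
    "mpf_learning_step",
]


@dataclass(frozen=True)
class FlowValue:
    value: float
    per_pattern: np.ndarray | None = None

    def __post_init__(self):
        if self.value < 0:
            raise ValueError("probability flow is a sum of exponentials, must be >= 0")


@dataclass(frozen=True)
class FitResult:
    network: HopfieldNetwork
    final_flow: float
    iterations: int
    converged: bool
    message: str = ""


def _pattern_matrix(X, n: int | None = None) -> np.ndarray:
    if isinstance(X, np.ndarray) and X.ndim == 2:
        rows = [as_state(row) for row in X]
    else:
        rows = [as_state(x) for x in X]
    if not rows:
        raise ValueError("training set must be nonempty")
    lengths = {r.shape[0] for r in rows}
    if len(lengths) != 1:
        raise ValueError(f"patterns have mixed lengths {sorted(lengths)}")
    m = np.vstack(rows).astype(float)
    if n is not None and m.shape[1] != n:
        raise ValueError(f"pattern length {m.shape[1]} does not match network size {n}")
    return m


def _exponent_terms(Xm: np.ndarray, net: HopfieldNetwork):
    D = 1.0 - 2.0 * Xm                     # flip direction per bit
    G = Xm @ net.W - net.theta             # I_e - theta_e for every pattern/bit
    A = np.exp(0.5 * D * G)
    return D, A


def probability_flow(X, net: HopfieldNetwork, method: str = "inputs") -> FlowValue:
    """Evaluate the flow objective over training patterns ``X``.

    ``method='inputs'`` uses the O(n) single-flip energy difference per bit;
    ``method='naive'`` recomputes both energies per neighbor (the slow oracle
    used to validate the shortcut).
    """
    Xm = _pattern_matrix(X, net.n)
    if method == "inputs":
        _, A = _exponent_terms(Xm, net)
        per = A.sum(axis=1)
    elif method == "naive":
        from .core import energy

        per = np.empty(Xm.shape[0])
        for r, xf in enumerate(Xm):
            x = xf.astype(np.uint8)
            e_x = energy(x, net)
            total = 0.0
            for e in range(net.n):
                x2 = x.copy()
                x2[e] ^= 1
                total += np.exp((e_x - energy(x2, net)) / 2.0)
            per[r] = total
    else:
        raise ValueError(f"unknown method {method!r}")
    return FlowValue(float(per.mean()), per)


def probability_flow_gradient(X, net: HopfieldNetwork):
    """Analytic gradient (dW, dtheta) of the flow objective.

    dW is symmetric with zero diagonal: the (e, f) entry is the derivative
    with respect to the single tied parameter W_ef = W_fe.
    """
    Xm = _pattern_matrix(X, net.n)
    m = Xm.shape[0]
    D, A = _exponent_terms(Xm, net)
    DA = D * A
    dtheta = -DA.sum(axis=0) / (2.0 * m)
    B = DA.T @ Xm / (2.0 * m)
    dW = B + B.T
    np.fill_diagonal(dW, 0.0)
    return dW, dtheta


def _pack(W: np.ndarray, theta: np.ndarray, iu) -> np.ndarray:
    return np.concatenate([W[iu], theta])


def _unpack(params: np.ndarray, n: int, iu) -> tuple[np.ndarray, np.ndarray]:
    W = np.zeros((n, n))
    W[iu] = params[: iu[0].size]
    W = W + W.T
    return W, params[iu[0].size:]


def fit_mpf(
    X,
    init: HopfieldNetwork | str = "zeros",
    max_iter: int = 500,
    grad_tol: float = 1e-6,
    seed=None,
    gauss_scale: float = 0.1,
) -> FitResult:
    """Minimize the flow over the free parameters (upper triangle of W, theta).

    Symmetry and the zero diagonal are enforced by the parameterization
    itself.  ``init`` may be a network, "zeros" (from which the initial flow
    equals n per pattern, a built-in self-check), or "gauss" (seeded).
    """
    Xm = _pattern_matrix(X)
    n = Xm.shape[1]
    iu = np.triu_indices(n, 1)

    if isinstance(init, HopfieldNetwork):
        if init.n != n:
            raise ValueError("init network size does not match patterns")
        x0 = _pack(init.W, init.theta, iu)
    elif init == "zeros":
        x0 = np.zeros(iu[0].size + n)
    elif init == "gauss":
        rng = np.random.default_rng(seed)
        x0 = rng.normal(scale=gauss_scale, size=iu[0].size + n)
    else:
        raise ValueError(f"unknown init {init!r}")

    D = 1.0 - 2.0 * Xm
    m = Xm.shape[0]

    def objective(params):
        W, theta = _unpack(params, n, iu)
        G = Xm @ W - theta
        A = np.exp(0.5 * D * G)
        value = A.sum() / m
        DA = D * A
        dtheta = -DA.sum(axis=0) / (2.0 * m)
        B = DA.T @ Xm / (2.0 * m)
        dW = B + B.T
        return value, np.concatenate([dW[iu], dtheta])

    res = minimize(
        objective,
        x0,
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": max_iter, "gtol": grad_tol, "maxcor": 20},
    )
    W, theta = _unpack(res.x, n, iu)
    net = HopfieldNetwork(W, theta)
    return FitResult(net, float(res.fun), int(res.nit), bool(res.success), str(res.message))


def mpf_learning_step(x, net: HopfieldNetwork, rate: float) -> HopfieldNetwork:
    """One local flow-descent update from a single pattern.

    For every neuron e the proposed one-step update under the *current*
    network defines the bit change dx_e in {-1, 0, +1} and the energy change
    dE_e = -dx_e (I_e - theta_e); then

        dW_ef = -rate * x_f * dx_e * exp(-dE_e / 2)   (e != f),
        dtheta_e =  rate * dx_e * exp(-dE_e / 2).

    Weights are symmetrized to (W_ef + W_fe)/2 afterwards and the diagonal is
    forced to zero, which preserves the energy function.  A memorized pattern
    (dx = 0 everywhere) leaves the network unchanged.
    """
    if rate <= 0:
        raise ValueError("rate must be positive")
    x = as_state(x)
    if x.shape[0] != net.n:
        raise ValueError("pattern length does not match network")
    xf = x.astype(float)
    I = net.W @ xf
    proposed = (I > net.theta).astype(float)
    dx = proposed - xf
    dE = -dx * (I - net.theta)
    factor = dx * np.exp(-dE / 2.0)
    dW = -rate * np.outer(factor, xf)
    np.fill_diagonal(dW, 0.0)
    W = net.W + dW
    W = 0.5 * (W + W.T)
    np.fill_diagonal(W, 0.0)
    theta = net.theta + rate * factor
    return HopfieldNetwork(W, theta)
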