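"""Binary Hopfield networks: energy, asynchronous threshold dynamics, corruption.

A network is a symmetric zero-diagonal weight matrix ``W`` together with a
threshold vector ``theta``.  States are length-``n`` 0/1 vectors.  The
deterministic dynamics visits neurons in some order and sets bit ``e`` to 1
exactly when its feedforward input strictly exceeds ``theta[e]`` (ties map to
0).  Each such update can only lower the energy

    E(x) = -1/2 x^T W x + theta^T x,

so repeated sweeps terminate in a fixed point.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "BinaryState",
    "HopfieldNetwork",
    "DynamicsResult",
    "CorruptionSpec",
    "ConvergenceError",
    "as_state",
    "energy",
    "feedforward_input",
    "update_neuron",
    "sweep",
    "converge",
    "sweep_batch",
    "converge_batch",
    "p_corrupt",
    "state_to_text",
    "state_from_text",
    "save_network",
    "load_network",
]

#: A binary state is simply a 1-D uint8 array with entries in {0, 1}.
BinaryState = np.ndarray


class ConvergenceError(RuntimeError):
    """Raised when dynamics fails to reach a fixed point within ``max_sweeps``.

    For symmetric zero-diagonal weights this is unreachable; hitting it
    signals a violated invariant (e.g. a tampered weight matrix).
    """


def as_state(bits) -> BinaryState:
    """Validate and normalize ``bits`` into a uint8 0/1 vector."""
    arr = np.asarray(bits)
    if arr.dtype == bool:
        arr = arr.astype(np.uint8)
    if arr.ndim != 1:
        raise ValueError(f"state must be 1-D, got shape {arr.shape}")
    if arr.size == 0:
        raise ValueError("state must be nonempty")
    out = arr.astype(np.uint8)
    if not np.array_equal(out, arr) or not np.isin(out, (0, 1)).all():
        raise ValueError("state entries must be exactly 0 or 1")
    return out.copy()


@dataclass(frozen=True)
class HopfieldNetwork:
    """Symmetric zero-diagonal weights ``W`` and thresholds ``theta``."""

    W: np.ndarray
    theta: np.ndarray

    def __post_init__(self):
        W = np.asarray(self.W, dtype=float)
        theta = np.asarray(self.theta, dtype=float)
        if W.ndim != 2 or W.shape[0] != W.shape[1]:
            raise ValueError(f"W must be square, got shape {W.shape}")
        if theta.shape != (W.shape[0],):
            raise ValueError(
                f"theta length {theta.shape} does not match W of order {W.shape[0]}"
            )
        if not np.allclose(W, W.T, atol=0.0):
            raise ValueError("W must be exactly symmetric")
        if np.any(np.diag(W) != 0.0):
            raise ValueError("W must have a zero diagonal")
        object.__setattr__(self, "W", W)
        object.__setattr__(self, "theta", theta)

    @property
    def n(self) -> int:
        return self.W.shape[0]

    @classmethod
    def zeros(cls, n: int) -> "HopfieldNetwork":
        return cls(np.zeros((n, n)), np.zeros(n))


@dataclass(frozen=True)
class DynamicsResult:
    """Outcome of iterating sweeps to a fixed point."""

    fixed_point: BinaryState
    sweeps: int
    energy_trace: tuple


@dataclass(frozen=True)
class CorruptionSpec:
    """Independent per-bit flip probability ``p`` with a fixed RNG seed."""

    p: float
    seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.p <= 0.5):
            raise ValueError(f"corruption probability must lie in [0, 1/2], got {self.p}")


def _check_state(state: BinaryState, net: HopfieldNetwork) -> None:
    if state.shape != (net.n,):
        raise ValueError(
            f"state length {state.shape[0] if state.ndim == 1 else state.shape} "
            f"does not match network size {net.n}"
        )


def energy(state: BinaryState, net: HopfieldNetwork) -> float:
    """Return ``-1/2 x^T W x + theta^T x``."""
    _check_state(state, net)
    x = state.astype(float)
    return float(-0.5 * x @ net.W @ x + net.theta @ x)


def feedforward_input(state: BinaryState, net: HopfieldNetwork, e: int) -> float:
    """Return ``<W_e, x>``; the diagonal is zero so self-input never contributes."""
    _check_state(state, net)
    if not (0 <= e < net.n):
        raise IndexError(f"neuron index {e} out of range for n={net.n}")
    return float(net.W[e] @ state.astype(float))


def update_neuron(
    state: BinaryState, net: HopfieldNetwork, e: int
) -> tuple[BinaryState, bool]:
    """Apply the threshold rule at neuron ``e``: new bit is 1 iff I_e > theta_e.

    Ties (``I_e == theta_e``) yield 0.  Returns the new state and whether the
    bit changed.
    """
    I_e = feedforward_input(state, net, e)
    new_bit = 1 if I_e > net.theta[e] else 0
    changed = new_bit != state[e]
    out = state.copy()
    out[e] = new_bit
    return out, changed


def _check_order(order, n: int) -> np.ndarray:
    order = np.asarray(order)
    if order.shape != (n,) or not np.array_equal(np.sort(order), np.arange(n)):
        raise ValueError("order must be a permutation of 0..n-1")
    return order


def sweep(state: BinaryState, net: HopfieldNetwork, order=None) -> BinaryState:
    """One full pass through all neurons in ``order`` (default ascending).

    Updates are asynchronous: each neuron sees the effect of all previous
    updates within the sweep.
    """
    _check_state(state, net)
    n = net.n
    order = np.arange(n) if order is None else _check_order(order, n)
    x = state.astype(float)
    W, theta = net.W, net.theta
    for e in order:
        x[e] = 1.0 if W[e] @ x > theta[e] else 0.0
    return x.astype(np.uint8)


def _sweep_orders(n: int, order_policy: str, seed):
    """Yield one neuron order per sweep under the given policy."""
    if order_policy == "ascending":
        fixed = np.arange(n)
        while True:
            yield fixed
    elif order_policy == "random":
        rng = np.random.default_rng(seed)
        while True:
            yield rng.permutation(n)
    else:
        raise ValueError(f"unknown order policy {order_policy!r}")


def converge(
    state: BinaryState,
    net: HopfieldNetwork,
    order_policy: str = "ascending",
    seed=None,
    max_sweeps: int | None = None,
) -> DynamicsResult:
    """Sweep until one full pass changes no bit.

    ``sweeps`` counts every pass performed, including the final idle one, so a
    fixed-point input reports ``sweeps == 1``.  The energy trace (one entry
    per sweep) is non-increasing.
    """
    _check_state(state, net)
    max_sweeps = net.n if max_sweeps is None else max_sweeps
    if max_sweeps < 1:
        raise ValueError("max_sweeps must be >= 1")
    orders = _sweep_orders(net.n, order_policy, seed)
    x = state.copy()
    trace = []
    for s in range(1, max_sweeps + 1):
        new = sweep(x, net, next(orders))
        trace.append(energy(new, net))
        if np.array_equal(new, x):
            return DynamicsResult(new, s, tuple(trace))
        x = new
    raise ConvergenceError(
        f"no fixed point within {max_sweeps} sweeps; "
        "this should be unreachable for symmetric zero-diagonal weights"
    )


def sweep_batch(S: np.ndarray, net: HopfieldNetwork, order=None) -> np.ndarray:
    """Vectorized sweep of many states at once (rows of float matrix ``S``).

    All rows share the same neuron order; each row evolves independently.
    Modifies ``S`` in place and returns it.
    """
    n = net.n
    if S.ndim != 2 or S.shape[1] != n:
        raise ValueError(f"batch must have shape (m, {n})")
    order = np.arange(n) if order is None else _check_order(order, n)
    W, theta = net.W, net.theta
    for e in order:
        S[:, e] = S @ W[:, e] > theta[e]
    return S


def converge_batch(
    states: np.ndarray,
    net: HopfieldNetwork,
    order_policy: str = "ascending",
    seed=None,
    max_sweeps: int | None = None,
) -> tuple[np.ndarray, int]:
    """Run every row of ``states`` to a fixed point; returns (uint8 matrix, sweeps)."""
    S = np.asarray(states, dtype=float).copy()
    max_sweeps = net.n if max_sweeps is None else max_sweeps
    orders = _sweep_orders(net.n, order_policy, seed)
    for s in range(1, max_sweeps + 1):
        before = S.copy()
        sweep_batch(S, net, next(orders))
        if np.array_equal(S, before):
            return S.astype(np.uint8), s
    raise ConvergenceError(f"batch did not converge within {max_sweeps} sweeps")


def p_corrupt(state: BinaryState, spec: CorruptionSpec) -> BinaryState:
    """Flip each bit independently with probability ``spec.p`` (seeded)."""
    state = as_state(state)
    rng = np.random.default_rng(spec.seed)
    flips = rng.random(state.shape[0]) < spec.p
    return (state ^ flips.astype(np.uint8)).astype(np.uint8)


# --- plain-text serialization ------------------------------------------------

def state_to_text(state: BinaryState) -> str:
    """A state is one line of '0'/'1' characters with no separators."""
    return "".join("1" if b else "0" for b in as_state(state))


def state_from_text(text: str) -> BinaryState:
    line = text.strip()
    if not line or set(line) - {"0", "1"}:
        raise ValueError("state text must be a nonempty string of 0/1 characters")
    return np.frombuffer(line.encode(), dtype=np.uint8) - ord("0")


def save_network(net: HopfieldNetwork, path) -> None:
    """Write: line 1 is n, then n rows of W, then one row of theta."""
    with open(path, "w") as fh:
        fh.write(f"{net.n}\n")
        for row in net.W:
            fh.write(" ".join(repr(float(w)) for w in row) + "\n")
        fh.write(" ".join(repr(float(t)) for t in net.theta) + "\n")


def load_network(path) -> HopfieldNetwork:
    with open(path) as fh:
        n = int(fh.readline())
        rows = [np.array(fh.readline().split(), dtype=float) for _ in range(n)]
        theta = np.array(fh.readline().split(), dtype=float)
    return HopfieldNetwork(np.vstack(rows), theta)
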