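"""Limits of networks storing all permutations of k letters.

A permutation sigma is represented as a length k(k-1) binary vector over the
off-diagonal ordered pairs (i, j), i != j, in row-major order, with a 1 at
(i, j) exactly when sigma(i) = j.  Because the diagonal is excluded,
permutations with fixed points are not representable; derangements are.

For a derangement there are k(k-2) "critical pairs" (i, j): adding edge ij
and dropping edge i->sigma(i) produces a pattern two bit flips from sigma and
two flips from a second permutation with exactly two cycles.  A random
corruption that lands on such a midpoint is an indistinguishable input for
*any* network storing all permutations, which bounds below the failure
probability of recovering derangements from noise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import BinaryState, CorruptionSpec, as_state, p_corrupt

__all__ = [
    "PermutationState",
    "CriticalPair",
    "pair_slot",
    "slot_pair",
    "encode_permutation",
    "decode_permutation",
    "is_derangement",
    "random_derangement",
    "cycle_count",
    "critical_pair",
    "all_critical_pairs",
    "indistinguishability_bound",
    "monte_carlo_indistinguishable",
    "read_permutation_line",
    "write_permutation_line",
]


@dataclass(frozen=True)
class PermutationState:
    k: int
    bits: BinaryState

    def __post_init__(self):
        bits = as_state(self.bits)
        if bits.shape[0] != self.k * (self.k - 1):
            raise ValueError(f"need k(k-1) = {self.k * (self.k - 1)} bits")
        object.__setattr__(self, "bits", bits)
        decode_permutation(bits, self.k)  # validates one 1 per row and column


def pair_slot(i: int, j: int, k: int) -> int:
    """Row-major index of the ordered off-diagonal pair (i, j), 0-based."""
    if not (0 <= i < k and 0 <= j < k) or i == j:
        raise ValueError(f"need distinct letters in range, got ({i}, {j}), k={k}")
    return i * (k - 1) + (j if j < i else j - 1)


def slot_pair(slot: int, k: int) -> tuple[int, int]:
    if not (0 <= slot < k * (k - 1)):
        raise ValueError("slot out of range")
    i, rem = divmod(slot, k - 1)
    j = rem if rem < i else rem + 1
    return i, j


def _as_perm(sigma) -> np.ndarray:
    arr = np.asarray(sigma, dtype=int)
    k = arr.shape[0]
    if arr.ndim != 1 or not np.array_equal(np.sort(arr), np.arange(k)):
        raise ValueError("sigma must be a bijection given as the image vector")
    return arr


def is_derangement(sigma) -> bool:
    arr = _as_perm(sigma)
    return bool(np.all(arr != np.arange(arr.shape[0])))


def encode_permutation(sigma) -> PermutationState:
    """Encode a fixed-point-free permutation; any fixed point would require a
    diagonal slot and is rejected."""
    arr = _as_perm(sigma)
    k = arr.shape[0]
    if not is_derangement(arr):
        raise ValueError("permutations with fixed points are not representable")
    bits = np.zeros(k * (k - 1), dtype=np.uint8)
    for i, j in enumerate(arr):
        bits[pair_slot(i, int(j), k)] = 1
    return PermutationState(k, bits)


def decode_permutation(bits: BinaryState, k: int) -> np.ndarray:
    """Inverse of encode; raises if bits do not describe a bijection."""
    bits = as_state(bits)
    if bits.shape[0] != k * (k - 1):
        raise ValueError("length must be k(k-1)")
    image = np.full(k, -1, dtype=int)
    seen_targets = set()
    for slot in np.flatnonzero(bits):
        i, j = slot_pair(int(slot), k)
        if image[i] != -1:
            raise ValueError(f"letter {i} has two images")
        if j in seen_targets:
            raise ValueError(f"letter {j} has two preimages")
        image[i] = j
        seen_targets.add(j)
    if np.any(image < 0):
        raise ValueError("some letter has no image")
    return image


def random_derangement(k: int, rng=None) -> np.ndarray:
    """Uniform derangement by rejection."""
    if k < 2:
        raise ValueError("no derangements for k < 2")
    rng = np.random.default_rng(rng)
    while True:
        perm = rng.permutation(k)
        if np.all(perm != np.arange(k)):
            return perm


def cycle_count(sigma) -> int:
    arr = _as_perm(sigma)
    seen = np.zeros(arr.shape[0], dtype=bool)
    count = 0
    for start in range(arr.shape[0]):
        if seen[start]:
            continue
        count += 1
        t = start
        while not seen[t]:
            seen[t] = True
            t = int(arr[t])
    return count


@dataclass(frozen=True)
class CriticalPair:
    i: int
    j: int
    y_pattern: BinaryState  # two flips from both endpoints
    x_alt: PermutationState  # the competing two-cycle permutation
    critical_edges: tuple  # the four modified slots


def critical_pair(sigma, i: int, j: int) -> CriticalPair:
    """Construct the midpoint pattern and competing permutation for (i, j).

    Flips, in order: add edge i->j, drop i->sigma(i) (giving the midpoint),
    then drop sigma^{-1}(j)->j and add sigma^{-1}(j)->sigma(i) (giving a
    permutation with the (i, j) transposition structure merged in).
    """
    arr = _as_perm(sigma)
    if not is_derangement(arr):
        raise ValueError("sigma must be a derangement")
    k = arr.shape[0]
    if i == j:
        raise ValueError("need i != j")
    if int(arr[i]) == j:
        raise ValueError("need j != sigma(i)")
    si = int(arr[i])
    inv_j = int(np.flatnonzero(arr == j)[0])
    if inv_j == si:
        # j = sigma(sigma(i)): the competing permutation would fix the letter
        # sigma(i), which has no off-diagonal slot and so is not representable
        raise ValueError(
            "degenerate pair: j = sigma(sigma(i)) yields a fixed point; "
            "not representable without diagonal slots"
        )
    base = encode_permutation(arr)
    s_add1 = pair_slot(i, j, k)
    s_drop1 = pair_slot(i, si, k)
    s_drop2 = pair_slot(inv_j, j, k)
    s_add2 = pair_slot(inv_j, si, k)
    y = base.bits.copy()
    y[s_add1] ^= 1
    y[s_drop1] ^= 1
    alt_bits = y.copy()
    alt_bits[s_drop2] ^= 1
    alt_bits[s_add2] ^= 1
    alt = PermutationState(k, alt_bits)
    return CriticalPair(i, j, y, alt, (s_drop1, s_add1, s_drop2, s_add2))


def all_critical_pairs(sigma, skip_degenerate: bool = True) -> list[CriticalPair]:
    """All valid critical pairs of a derangement.

    For an involution (all cycles of length 2) there are exactly k(k-2).
    For letters in longer cycles the choice j = sigma(sigma(i)) is degenerate
    (see :func:`critical_pair`) and is skipped when ``skip_degenerate``.
    """
    arr = _as_perm(sigma)
    out = []
    for i in range(arr.shape[0]):
        for j in range(arr.shape[0]):
            if j == i or j == int(arr[i]):
                continue
            if int(arr[int(arr[i])]) == j:
                if skip_degenerate:
                    continue
                raise ValueError(f"degenerate pair ({i}, {j})")
            out.append(critical_pair(arr, i, j))
    return out


def matching_derangement(k: int) -> np.ndarray:
    """The involution (0 1)(2 3)...: every pair construction is non-degenerate,
    so the critical-pair count is exactly k(k-2)."""
    if k < 2 or k % 2:
        raise ValueError("need even k >= 2")
    arr = np.arange(k)
    arr[0::2] += 1
    arr[1::2] -= 1
    return arr


def indistinguishability_bound(p: float, k: int) -> tuple[float, float]:
    """(exact_pair, lower_bound) failure-probability bounds at corruption p.

    exact_pair = 1 - (1 - 4(1-p)^2 p^2)^(k(k-2)) uses the per-pair coupling
    probability and disjointness of critical edges; lower_bound is the looser
    displayed form 1 - (1 - 4 p^2)^(n/2) with n = k(k-1).  The first exceeds
    the second (verified numerically, not asserted here).
    """
    if not (0.0 < p < 0.5):
        raise ValueError("need 0 < p < 1/2")
    q = 4.0 * (1.0 - p) ** 2 * p * p
    exact_pair = 1.0 - (1.0 - q) ** (k * (k - 2))
    n = k * (k - 1)
    lower = 1.0 - (1.0 - 4.0 * p * p) ** (n / 2.0)
    return exact_pair, lower


def _critical_slot_matrix(sigma) -> np.ndarray:
    pairs = all_critical_pairs(sigma)
    return np.array([cp.critical_edges for cp in pairs], dtype=int)


def monte_carlo_indistinguishable(
    sigma, p: float, trials: int, seed: int = 0
) -> float:
    """Frequency with which a p-corruption of sigma's state is an
    indistinguishable midpoint for at least one critical pair.

    The per-pair event: among the pair's four critical slots, exactly one of
    the two slots carrying an edge of sigma is flipped off and exactly one of
    the two slots carrying an edge of the competing permutation is flipped
    on.  Each of the four flip combinations has probability p^2 (1-p)^2, so
    the per-pair probability is 4(1-p)^2 p^2 exactly, and disjointness of
    critical edges across pairs makes the union probability
    1 - (1 - 4(1-p)^2 p^2)^(k(k-2)).
    """
    if trials < 1:
        raise ValueError("trials must be >= 1")
    if not (0.0 < p < 0.5):
        raise ValueError("need 0 < p < 1/2")
    arr = _as_perm(sigma)
    slots = _critical_slot_matrix(arr)  # (num_pairs, 4): drop1, add1, drop2, add2
    n = arr.shape[0] * (arr.shape[0] - 1)
    rng = np.random.default_rng(seed)
    hits = 0
    batch = 2000
    done = 0
    while done < trials:
        b = min(batch, trials - done)
        flips = rng.random((b, n)) < p
        f = flips[:, slots]  # (b, num_pairs, 4)
        drops = f[:, :, 0].astype(int) + f[:, :, 2]
        adds = f[:, :, 1].astype(int) + f[:, :, 3]
        event = (drops == 1) & (adds == 1)
        hits += int(event.any(axis=1).sum())
        done += b
    return hits / trials


def write_permutation_line(sigma) -> str:
    """One-line 1-based image: 'sigma(1) sigma(2) ... sigma(k)'."""
    arr = _as_perm(sigma)
    return " ".join(str(int(t) + 1) for t in arr)


def read_permutation_line(line: str) -> np.ndarray:
    vals = np.array(line.split(), dtype=int) - 1
    return _as_perm(vals)
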