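"""Graphs on v vertices as binary states of length n = v(v-1)/2.

Vertices are 0-based.  Edges are ordered lexicographically:
(0,1) -> 0, (0,2) -> 1, ..., (v-2, v-1) -> n-1, which is exactly the order of
``numpy.triu_indices(v, 1)``.  All serialization uses this convention.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from functools import lru_cache

import networkx as nx
import numpy as np

from .core import BinaryState, as_state

__all__ = [
    "GraphStats",
    "edge_count",
    "pair_table",
    "edge_index",
    "index_edge",
    "vertex_count",
    "clique_state",
    "clique_vertices",
    "state_to_graph",
    "graph_to_state",
    "graph_stats",
    "count_cliques",
    "asymptotic_count",
    "random_cliques",
    "write_edge_list",
    "read_edge_list",
    "write_adjacency",
    "read_adjacency",
    "state_degrees",
]


def edge_count(v: int) -> int:
    """Number of vertex pairs, v(v-1)/2."""
    if v < 2:
        raise ValueError("need at least two vertices")
    return v * (v - 1) // 2


@lru_cache(maxsize=64)
def pair_table(v: int) -> tuple[np.ndarray, np.ndarray]:
    """Arrays (I, J) with I[e] < J[e] listing pair e in lexicographic order."""
    if v < 2:
        raise ValueError("need at least two vertices")
    i, j = np.triu_indices(v, 1)
    i.setflags(write=False)
    j.setflags(write=False)
    return i, j


def edge_index(i: int, j: int, v: int) -> int:
    """Lexicographic rank of the pair (i, j), requiring 0 <= i < j < v."""
    if not (0 <= i < j < v):
        raise ValueError(f"need 0 <= i < j < v, got ({i}, {j}) with v={v}")
    return i * (2 * v - i - 1) // 2 + (j - i - 1)


def index_edge(idx: int, v: int) -> tuple[int, int]:
    """Inverse of :func:`edge_index`."""
    n = edge_count(v)
    if not (0 <= idx < n):
        raise ValueError(f"edge index {idx} out of range for v={v}")
    # row starts: start(i) = i*(2v-i-1)/2, increasing in i
    starts = np.array([i * (2 * v - i - 1) // 2 for i in range(v - 1)])
    i = int(np.searchsorted(starts, idx, side="right")) - 1
    j = idx - int(starts[i]) + i + 1
    return i, j


def vertex_count(n: int) -> int:
    """Recover v from n = v(v-1)/2, or raise if n is not triangular."""
    v = (1 + math.isqrt(1 + 8 * n)) // 2
    if edge_count(max(v, 2)) != n:
        raise ValueError(f"{n} is not of the form v(v-1)/2")
    return v


def clique_state(vertices, v: int) -> BinaryState:
    """State whose set bits are exactly the C(k,2) edges among ``vertices``."""
    verts = sorted(int(u) for u in vertices)
    if len(set(verts)) != len(verts):
        raise ValueError("clique vertices must be distinct")
    if len(verts) < 2:
        raise ValueError("a clique needs at least two vertices")
    if verts[0] < 0 or verts[-1] >= v:
        raise ValueError("clique vertices out of range")
    bits = np.zeros(edge_count(v), dtype=np.uint8)
    for a, b in itertools.combinations(verts, 2):
        bits[edge_index(a, b, v)] = 1
    return bits


def clique_vertices(state: BinaryState, v: int) -> list[int]:
    """Vertices incident to at least one edge (the support of the graph)."""
    deg = state_degrees(state, v)
    return [int(u) for u in np.flatnonzero(deg)]


def state_degrees(state: BinaryState, v: int) -> np.ndarray:
    """Degree sequence of the graph encoded by ``state``."""
    state = _check_length(state, v)
    I, J = pair_table(v)
    deg = np.zeros(v, dtype=np.int64)
    np.add.at(deg, I, state)
    np.add.at(deg, J, state)
    return deg


def _check_length(state, v: int) -> BinaryState:
    state = as_state(state)
    if state.shape[0] != edge_count(v):
        raise ValueError(
            f"state length {state.shape[0]} does not match v={v} "
            f"(expected {edge_count(v)})"
        )
    return state


def state_to_graph(state: BinaryState, v: int) -> nx.Graph:
    state = _check_length(state, v)
    I, J = pair_table(v)
    G = nx.Graph()
    G.add_nodes_from(range(v))
    on = np.flatnonzero(state)
    G.add_edges_from(zip(I[on].tolist(), J[on].tolist()))
    return G


def graph_to_state(G: nx.Graph, v: int) -> BinaryState:
    bits = np.zeros(edge_count(v), dtype=np.uint8)
    for a, b in G.edges():
        a, b = (a, b) if a < b else (b, a)
        bits[edge_index(a, b, v)] = 1
    return bits


@dataclass(frozen=True)
class GraphStats:
    """Edge count and the pair counts entering the symmetric energy."""

    edge_count: int
    s1: int  # pairs of edges sharing exactly one vertex
    s0: int  # pairs of disjoint edges

    def __post_init__(self):
        total = self.edge_count * (self.edge_count - 1) // 2
        if self.s1 + self.s0 != total:
            raise ValueError("s1 + s0 must equal C(#E, 2) for a simple graph")


def graph_stats(state: BinaryState, v: int, method: str = "degree") -> GraphStats:
    """Count (#E, S1, S0) for the encoded graph.

    ``method='degree'`` uses S1 = sum_u C(deg(u), 2); ``method='pairs'``
    enumerates active edge pairs directly.  Both agree on every graph.
    """
    state = _check_length(state, v)
    m = int(state.sum())
    if method == "degree":
        deg = state_degrees(state, v)
        s1 = int((deg * (deg - 1) // 2).sum())
    elif method == "pairs":
        I, J = pair_table(v)
        on = np.flatnonzero(state)
        s1 = 0
        for a, b in itertools.combinations(on, 2):
            if len({int(I[a]), int(J[a])} & {int(I[b]), int(J[b])}) == 1:
                s1 += 1
    else:
        raise ValueError(f"unknown method {method!r}")
    s0 = m * (m - 1) // 2 - s1
    return GraphStats(m, s1, s0)


def count_cliques(v: int, k: int) -> int:
    """Exact number of k-cliques on v labeled vertices, C(v, k)."""
    if not (2 <= k <= v):
        raise ValueError(f"need 2 <= k <= v, got k={k}, v={v}")
    return math.comb(v, k)


def asymptotic_count(n: float) -> float:
    """Asymptotic clique count 2^(sqrt(2n)+1/4) / (n^(1/4) sqrt(pi))."""
    if n <= 0:
        raise ValueError("n must be positive")
    return 2.0 ** (math.sqrt(2.0 * n) + 0.25) / (n ** 0.25 * math.sqrt(math.pi))


def random_cliques(
    v: int,
    k: int,
    count: int,
    seed=None,
    distinct: bool = False,
    rng: np.random.Generator | None = None,
) -> list[BinaryState]:
    """Draw ``count`` uniform k-subsets of the v vertices as clique states."""
    if count < 1:
        raise ValueError("count must be >= 1")
    total = count_cliques(v, k)
    if distinct and count > total:
        raise ValueError(f"cannot draw {count} distinct {k}-cliques from {total}")
    rng = np.random.default_rng(seed) if rng is None else rng
    if distinct and count > total // 2:
        if total > 10**6:
            raise ValueError(
                "distinct sampling close to exhaustion requires enumeration, "
                f"refused for C({v},{k}) = {total} > 1e6 subsets"
            )
        all_sets = list(itertools.combinations(range(v), k))
        chosen = rng.choice(len(all_sets), size=count, replace=False)
        return [clique_state(all_sets[c], v) for c in chosen]
    out, seen = [], set()
    while len(out) < count:
        verts = tuple(sorted(rng.choice(v, size=k, replace=False).tolist()))
        if distinct:
            if verts in seen:
                continue
            seen.add(verts)
        out.append(clique_state(verts, v))
    return out


# --- text formats ------------------------------------------------------------

def write_edge_list(state: BinaryState, v: int, path) -> None:
    """One 0-based 'i j' pair per line."""
    state = _check_length(state, v)
    I, J = pair_table(v)
    with open(path, "w") as fh:
        for e in np.flatnonzero(state):
            fh.write(f"{I[e]} {J[e]}\n")


def read_edge_list(path, v: int) -> BinaryState:
    bits = np.zeros(edge_count(v), dtype=np.uint8)
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            a, b = (int(t) for t in line.split())
            if a == b:
                raise ValueError(f"self-loop {a} {b} not allowed")
            a, b = (a, b) if a < b else (b, a)
            bits[edge_index(a, b, v)] = 1
    return bits


def write_adjacency(state: BinaryState, v: int, path) -> None:
    """Dense 0/1 adjacency matrix, one row per line."""
    state = _check_length(state, v)
    I, J = pair_table(v)
    A = np.zeros((v, v), dtype=np.uint8)
    on = np.flatnonzero(state)
    A[I[on], J[on]] = 1
    A[J[on], I[on]] = 1
    np.savetxt(path, A, fmt="%d")


def read_adjacency(path) -> tuple[BinaryState, int]:
    A = np.loadtxt(path, dtype=np.uint8)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("adjacency matrix must be square")
    if not np.array_equal(A, A.T) or np.any(np.diag(A) != 0):
        raise ValueError("adjacency matrix must be symmetric with zero diagonal")
    v = A.shape[0]
    I, J = pair_table(v)
    return A[I, J].astype(np.uint8), v
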