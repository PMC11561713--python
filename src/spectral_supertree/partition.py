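"""Graph bipartitioning across the normalized-cut bottleneck.

The normalized cut of a bipartition (A, B) of a weighted graph is

    Ncut(A, B) = W(A,B)/W(A,V) + W(A,B)/W(B,V)

with W(X,Y) the sum of w(x,y) over ordered pairs x in X, y in Y — the
classical convention under which W(A,V) is the volume of A (within-block
edges counted twice, cut edges once).  Minimising Ncut exactly is
NP-complete; the spectral relaxation embeds vertices by the second
eigenvector of the (symmetric) normalized Laplacian and clusters the 1-D
embedding with 2-means.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
from scipy.linalg import eigh
from scipy.sparse import csr_matrix, identity
from scipy.sparse.linalg import eigsh
from sklearn.cluster import KMeans

from .graph import ProperClusterGraph

__all__ = [
    "Bipartition",
    "connected_components",
    "ncut_value",
    "spectral_bipartition",
    "brute_force_min_ncut",
]


@dataclass(frozen=True)
class Bipartition:
    """A two-block split of graph vertices (by vertex index)."""

    block_a: frozenset[int]
    block_b: frozenset[int]
    ncut: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.block_a or not self.block_b:
            raise ValueError("both blocks must be non-empty")
        if self.block_a & self.block_b:
            raise ValueError("blocks must be disjoint")


def _canonical_blocks(
    a: frozenset[int], b: frozenset[int]
) -> tuple[frozenset[int], frozenset[int]]:
    return (a, b) if min(a) < min(b) else (b, a)


def connected_components(graph: ProperClusterGraph) -> list[set[int]]:
    """Maximal connected components, as vertex-index sets, in canonical
    order (by smallest vertex index).  Isolated vertices are singletons."""
    n = graph.n_vertices
    seen = [False] * n
    components: list[set[int]] = []
    for start in range(n):
        if seen[start]:
            continue
        comp = {start}
        seen[start] = True
        frontier = [start]
        while frontier:
            node = frontier.pop()
            for nbr in graph.adj[node]:
                if not seen[nbr]:
                    seen[nbr] = True
                    comp.add(nbr)
                    frontier.append(nbr)
        components.append(comp)
    return components


def ncut_value(graph: ProperClusterGraph, split: Bipartition) -> float:
    """Evaluate the normalized cut of ``split`` on ``graph``."""
    if split.block_a | split.block_b != set(range(graph.n_vertices)):
        raise ValueError("bipartition must cover all graph vertices")
    in_a = split.block_a
    cut = 0.0
    for i, j, w in graph.edges():
        if (i in in_a) != (j in in_a):
            cut += w
    vol_a = sum(graph.degree_weight(i) for i in split.block_a)
    vol_b = sum(graph.degree_weight(i) for i in split.block_b)
    if vol_a == 0.0 or vol_b == 0.0:
        empty = "block_a" if vol_a == 0.0 else "block_b"
        raise ValueError(f"{empty} touches no edge: Ncut denominator is zero")
    if cut == 0.0:
        return 0.0
    return cut / vol_a + cut / vol_b


def _affinity_dense(graph: ProperClusterGraph) -> np.ndarray:
    n = graph.n_vertices
    W = np.zeros((n, n))
    for i, j, w in graph.edges():
        W[i, j] = W[j, i] = w
    return W


_DENSE_LIMIT = 512


def _fiedler_embedding(graph: ProperClusterGraph) -> np.ndarray:
    """Second-smallest generalized eigenvector of (L, D): the 1-D spectral
    embedding y = D^{-1/2} u2 with u2 from the symmetric normalized
    Laplacian."""
    n = graph.n_vertices
    deg = np.array([graph.degree_weight(i) for i in range(n)], dtype=float)
    if np.any(deg <= 0):
        raise ValueError("spectral bipartition requires a connected graph")
    d_isqrt = 1.0 / np.sqrt(deg)
    if n <= _DENSE_LIMIT:
        W = _affinity_dense(graph)
        L = np.eye(n) - (d_isqrt[:, None] * W) * d_isqrt[None, :]
        _vals, vecs = eigh(L, subset_by_index=[0, 1])
        u2 = vecs[:, 1]
    else:
        rows, cols, vals = [], [], []
        for i, j, w in graph.edges():
            rows.extend((i, j))
            cols.extend((j, i))
            vals.extend((w, w))
        W = csr_matrix((vals, (rows, cols)), shape=(n, n))
        Wn = csr_matrix(
            (np.asarray(vals) * d_isqrt[rows] * d_isqrt[cols], (rows, cols)),
            shape=(n, n),
        )
        L = identity(n, format="csr") - Wn
        # smallest eigenpairs of the PSD normalized Laplacian
        _vals, vecs = eigsh(L, k=2, sigma=-1e-6, which="LM")
        order = np.argsort(_vals)
        u2 = vecs[:, order[1]]
    return d_isqrt * u2


def spectral_bipartition(graph: ProperClusterGraph, seed: int = 0) -> Bipartition:
    """Bipartition a connected graph via the normalized-cut relaxation.

    The 1-D embedding is clustered with 2-means (10 restarts, seeded).
    A degenerate clustering collapsing to one block falls back to a split
    at the median embedding value, with exact ties resolved by canonical
    vertex order — the recursion that calls this must always shrink.
    """
    n = graph.n_vertices
    if n < 2:
        raise ValueError("spectral bipartition needs at least 2 vertices")
    if n == 2:
        return Bipartition(
            frozenset((0,)), frozenset((1,)),
            ncut=ncut_value(
                graph, Bipartition(frozenset((0,)), frozenset((1,)))
            ),
        )
    y = _fiedler_embedding(graph)
    km = KMeans(n_clusters=2, n_init=10, random_state=int(seed) % (2**31))
    labels = km.fit_predict(y.reshape(-1, 1))
    if len(set(labels)) < 2:
        labels = _median_split(y)
    a = frozenset(int(i) for i in np.nonzero(labels == labels[0])[0])
    b = frozenset(range(n)) - a
    if not b:
        labels = _median_split(y)
        a = frozenset(int(i) for i in np.nonzero(labels == labels[0])[0])
        b = frozenset(range(n)) - a
    a, b = _canonical_blocks(a, b)
    split = Bipartition(a, b)
    return Bipartition(a, b, ncut=ncut_value(graph, split))


def _median_split(y: np.ndarray) -> np.ndarray:
    order = np.lexsort((np.arange(len(y)), y))  # stable: ties by vertex index
    labels = np.zeros(len(y), dtype=int)
    labels[order[: len(y) // 2]] = 1
    return labels


_BRUTE_LIMIT = 18


def brute_force_min_ncut(graph: ProperClusterGraph) -> Bipartition:
    """Exhaustive minimum-Ncut bipartition (test oracle, <= 18 vertices).

    Ties are broken by the lexicographically smallest ``block_a`` (as a
    sorted vertex-index tuple).
    """
    n = graph.n_vertices
    if n < 2:
        raise ValueError("need at least 2 vertices")
    if n > _BRUTE_LIMIT:
        raise ValueError(f"refusing exhaustive enumeration beyond {_BRUTE_LIMIT} vertices")
    edges = list(graph.edges())
    deg = np.array([graph.degree_weight(i) for i in range(n)])
    best: tuple[float, tuple[int, ...]] | None = None
    full = set(range(n))
    for size_a in range(1, n // 2 + 1):
        for combo in combinations(range(n), size_a):
            a = set(combo)
            if size_a == n - size_a and 0 not in a:
                continue  # avoid double-counting complementary balanced splits
            cut = sum(w for i, j, w in edges if (i in a) != (j in a))
            vol_a = deg[list(a)].sum()
            vol_b = deg[list(full - a)].sum()
            if vol_a == 0 or vol_b == 0:
                continue
            val = cut / vol_a + cut / vol_b
            for cand in (tuple(sorted(a)), tuple(sorted(full - a))):
                key = (val, cand)
                if best is None or key < best:
                    best = key
    if best is None:
        raise ValueError("no valid bipartition (isolated blocks everywhere)")
    val, a_tuple = best
    a = frozenset(a_tuple)
    b = frozenset(full - a)
    return Bipartition(a, b, ncut=val)
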