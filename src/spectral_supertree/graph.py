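"""The weighted proper cluster graph and its contraction rules.

Two taxa form a *proper cluster* of a rooted tree when their connecting
path avoids the root — equivalently, their lowest common ancestor is a
non-root vertex.  The proper cluster graph over a multiset of source trees
has one vertex per taxon and an edge wherever some source tree exhibits the
pair as a proper cluster.  Edge weights aggregate per-tree support under
one of three strategies:

``unit``
    sum of the weights W_i of the trees exhibiting the pair;
``depth``
    sum of W_i times the edge-count depth of the pair's LCA in tree i
    (taxa absent from a tree fall back to the root, depth 0, contributing
    nothing);
``branch_length``
    as ``depth`` but with the LCA's branch-length distance from the root.

Vertices are groups of taxa: singletons initially, merged by contraction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterator, Optional, Sequence

from .tree import RootedTree, TreeNode

__all__ = [
    "WeightingStrategy",
    "ProperClusterGraph",
    "build_graph",
    "contraction_edges",
    "original_contraction_edges",
    "contract",
]

_KINDS = ("unit", "depth", "branch_length")


@dataclass(frozen=True)
class WeightingStrategy:
    """Edge-weighting rule plus optional per-tree confidence weights."""

    kind: str = "unit"
    tree_weights: Optional[Sequence[float]] = None

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"unknown weighting kind {self.kind!r}; expected one of {_KINDS}")
        if self.tree_weights is not None and any(w <= 0 for w in self.tree_weights):
            raise ValueError("tree weights must be positive")

    def weights_for(self, n_trees: int) -> list[float]:
        if self.tree_weights is None:
            return [1.0] * n_trees
        if len(self.tree_weights) != n_trees:
            raise ValueError(
                f"{len(self.tree_weights)} tree weights for {n_trees} source trees"
            )
        return [float(w) for w in self.tree_weights]


class ProperClusterGraph:
    """Weighted undirected graph whose vertices are disjoint taxon groups."""

    def __init__(self, groups: Sequence[frozenset[str]]) -> None:
        self.groups: list[frozenset[str]] = list(groups)
        seen: set[str] = set()
        for g in self.groups:
            if not g:
                raise ValueError("empty vertex group")
            if seen & g:
                raise ValueError("vertex groups must be disjoint")
            seen |= g
        self.adj: list[dict[int, float]] = [dict() for _ in self.groups]
        self.taxon_to_vertex: dict[str, int] = {
            t: i for i, g in enumerate(self.groups) for t in g
        }

    @property
    def n_vertices(self) -> int:
        return len(self.groups)

    @property
    def all_taxa(self) -> frozenset[str]:
        return frozenset(self.taxon_to_vertex)

    def add_edge_weight(self, i: int, j: int, w: float) -> None:
        if i == j:
            raise ValueError("self-loop")
        self.adj[i][j] = self.adj[i].get(j, 0.0) + w
        self.adj[j][i] = self.adj[j].get(i, 0.0) + w

    def set_edge(self, i: int, j: int, w: float) -> None:
        if i == j:
            raise ValueError("self-loop")
        self.adj[i][j] = w
        self.adj[j][i] = w

    def weight(self, i: int, j: int) -> float:
        return self.adj[i].get(j, 0.0)

    def edges(self) -> Iterator[tuple[int, int, float]]:
        for i, nbrs in enumerate(self.adj):
            for j, w in nbrs.items():
                if i < j:
                    yield i, j, w

    @property
    def n_edges(self) -> int:
        return sum(len(nbrs) for nbrs in self.adj) // 2

    def degree_weight(self, i: int) -> float:
        return sum(self.adj[i].values())

    def drop_nonpositive_edges(self) -> int:
        bad = [(i, j) for i, j, w in self.edges() if w <= 0]
        for i, j in bad:
            del self.adj[i][j]
            del self.adj[j][i]
        return len(bad)


# ---------------------------------------------------------------------------
# Construction
# ---------------------------------------------------------------------------


def _pair_weight_items(
    tree: RootedTree, kind: str
) -> Iterator[tuple[str, str, float]]:
    """Yield (u, v, f(lca)) for every proper-cluster pair of ``tree``.

    Each pair whose LCA lies below the root is yielded exactly once, at its
    exact LCA, with f = 1 (unit), edge depth, or branch-length root distance.
    """
    if kind == "branch_length" and not tree.has_branch_lengths:
        raise ValueError(
            "branch_length weighting requires branch lengths on every source tree"
        )
    # iterative postorder carrying depth / root length per node
    root = tree.root
    depth_of: dict[int, float] = {id(root): 0.0}
    order: list[TreeNode] = []
    stack = [root]
    while stack:
        node = stack.pop()
        order.append(node)
        for child in node.children:
            if kind == "depth":
                depth_of[id(child)] = depth_of[id(node)] + 1
            elif kind == "branch_length":
                depth_of[id(child)] = depth_of[id(node)] + (child.length or 0.0)
            stack.append(child)
    leaves_below: dict[int, list[str]] = {}
    for node in reversed(order):
        if node.is_leaf:
            leaves_below[id(node)] = [node.label]  # type: ignore[list-item]
            continue
        child_lists = [leaves_below[id(c)] for c in node.children]
        if node is not root:
            f = 1.0 if kind == "unit" else depth_of[id(node)]
            for a in range(len(child_lists)):
                for b in range(a + 1, len(child_lists)):
                    for u in child_lists[a]:
                        for v in child_lists[b]:
                            yield u, v, f
        merged: list[str] = []
        for cl in child_lists:
            merged.extend(cl)
        leaves_below[id(node)] = merged


def proper_cluster_pairs(tree: RootedTree) -> set[frozenset[str]]:
    """All taxon pairs forming a proper cluster of ``tree``."""
    return {frozenset((u, v)) for u, v, _ in _pair_weight_items(tree, "unit")}


def build_graph(
    trees: Sequence[RootedTree],
    strategy: WeightingStrategy | str = "unit",
    vertices: Optional[Sequence[str]] = None,
) -> ProperClusterGraph:
    """Build the weighted proper cluster graph for a multiset of source trees.

    ``vertices`` may supply extra taxa (beyond the union of tree leaf sets)
    that should appear as isolated vertices — the supertree recursion uses
    this for taxa whose only source tree shrank to a single leaf.
    """
    if not trees:
        raise ValueError("at least one source tree is required")
    if isinstance(strategy, str):
        strategy = WeightingStrategy(kind=strategy)
    tree_ws = strategy.weights_for(len(trees))
    taxa: set[str] = set()
    for t in trees:
        taxa |= t.taxa
    if vertices is not None:
        missing = taxa - set(vertices)
        if missing:
            raise ValueError(f"vertices must cover all tree taxa; missing {sorted(missing)[:5]}")
        taxa = set(vertices)
    ordered = sorted(taxa)
    graph = ProperClusterGraph([frozenset((t,)) for t in ordered])
    index = graph.taxon_to_vertex
    for tree, W in zip(trees, tree_ws):
        for u, v, f in _pair_weight_items(tree, strategy.kind):
            graph.add_edge_weight(index[u], index[v], W * f)
    dropped = graph.drop_nonpositive_edges()
    if dropped:
        warnings.warn(
            f"dropped {dropped} zero-weight proper-cluster edge(s) "
            "(LCA at zero branch-length distance from the root)",
            stacklevel=2,
        )
    return graph


# ---------------------------------------------------------------------------
# Contraction
# ---------------------------------------------------------------------------


def contraction_edges(
    trees: Sequence[RootedTree], graph: ProperClusterGraph
) -> set[tuple[int, int]]:
    """Edges eligible for contraction under the spectral method's rule.

    An edge (u, v) is contracted when every source tree containing *either*
    taxon contains both and exhibits them as a proper cluster.  A tree
    containing exactly one of the two taxa therefore blocks contraction.
    """
    trees_with: dict[str, set[int]] = {}
    for ti, tree in enumerate(trees):
        for taxon in tree.taxa:
            trees_with.setdefault(taxon, set()).add(ti)
    proper: list[set[frozenset[str]]] = [proper_cluster_pairs(t) for t in trees]
    out: set[tuple[int, int]] = set()
    for i, j, _w in graph.edges():
        if len(graph.groups[i]) != 1 or len(graph.groups[j]) != 1:
            raise ValueError("contraction rules apply to singleton-vertex graphs")
        (u,) = graph.groups[i]
        (v,) = graph.groups[j]
        pair = frozenset((u, v))
        relevant = trees_with.get(u, set()) | trees_with.get(v, set())
        if all(pair in proper[ti] for ti in relevant):
            out.add((i, j))
    return out


def original_contraction_edges(
    trees: Sequence[RootedTree],
    graph: ProperClusterGraph,
    tree_weights: Optional[Sequence[float]] = None,
) -> set[tuple[int, int]]:
    """Min-Cut Supertree's contraction rule: the pair is a proper cluster of
    *every* source tree (unit-weight support equals the total tree weight)."""
    n = len(trees)
    trees_with: dict[str, set[int]] = {}
    for ti, tree in enumerate(trees):
        for taxon in tree.taxa:
            trees_with.setdefault(taxon, set()).add(ti)
    proper_cache: dict[int, set[frozenset[str]]] = {}
    out: set[tuple[int, int]] = set()
    for i, j, _w in graph.edges():
        if len(graph.groups[i]) != 1 or len(graph.groups[j]) != 1:
            raise ValueError("contraction rules apply to singleton-vertex graphs")
        (u,) = graph.groups[i]
        (v,) = graph.groups[j]
        if len(trees_with.get(u, ())) != n or len(trees_with.get(v, ())) != n:
            continue
        pair = frozenset((u, v))
        ok = True
        for ti in range(n):
            if ti not in proper_cache:
                proper_cache[ti] = proper_cluster_pairs(trees[ti])
            if pair not in proper_cache[ti]:
                ok = False
                break
        if ok:
            out.add((i, j))
    return out


def contract(
    graph: ProperClusterGraph, edges: set[tuple[int, int]]
) -> ProperClusterGraph:
    """Contract the given edges (transitively), merging vertices into groups.

    Parallel edges arising from a merge keep only the maximal weight; no
    self-loops remain.  The union of taxa over vertex groups is conserved.
    """
    n = graph.n_vertices
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, j in edges:
        if graph.weight(i, j) == 0.0 and j not in graph.adj[i]:
            raise ValueError(f"contraction edge ({i},{j}) not in graph")
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[max(ri, rj)] = min(ri, rj)

    root_of = [find(i) for i in range(n)]
    new_groups_map: dict[int, set[str]] = {}
    for i, g in enumerate(graph.groups):
        new_groups_map.setdefault(root_of[i], set()).update(g)
    # canonical vertex order: by smallest taxon in the merged group
    roots = sorted(new_groups_map, key=lambda r: min(new_groups_map[r]))
    new_index = {r: k for k, r in enumerate(roots)}
    out = ProperClusterGraph([frozenset(new_groups_map[r]) for r in roots])
    for i, j, w in graph.edges():
        a, b = new_index[root_of[i]], new_index[root_of[j]]
        if a == b:
            continue
        if w > out.weight(a, b):
            out.set_edge(a, b, w)
    return out
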