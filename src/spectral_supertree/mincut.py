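"""Min-Cut Supertree: the ancestor of the spectral method, kept as a
baseline and cross-check.

The recursion skeleton is shared with the spectral method; what differs is
(a) the contraction rule — an edge is contracted only when *every* source
tree exhibits the pair as a proper cluster — and (b) the partitioning of a
connected graph, which removes minimum-cut edges instead of taking a
normalized cut:

``all_mincuts``
    every edge lying on any global minimum cut is removed (an edge e is on
    some min-cut iff mincut(G - e) == mincut(G) - w(e));
``single_mincut``
    only the edges crossing one deterministic minimum cut are removed (the
    cheaper variant used when all-min-cut removal is too expensive).

Removing min-cut edges always disconnects the graph, so the recursion then
proceeds on connected components exactly as in the spectral method.
"""

from __future__ import annotations

from typing import Optional, Sequence

import networkx as nx

from .graph import (
    ProperClusterGraph,
    WeightingStrategy,
    original_contraction_edges,
)
from .supertree import SupertreeProblem, _solve
from .tree import RootedTree

__all__ = ["edges_on_any_mincut", "mincut_supertree", "mincut_partition"]

_MODES = ("all_mincuts", "single_mincut")


def _to_networkx(graph: ProperClusterGraph) -> nx.Graph:
    G = nx.Graph()
    G.add_nodes_from(range(graph.n_vertices))
    for i, j, w in sorted(graph.edges()):
        G.add_edge(i, j, weight=w)
    return G


def edges_on_any_mincut(graph: ProperClusterGraph) -> set[tuple[int, int]]:
    """All edges lying on at least one global minimum weighted cut.

    Uses the per-edge test: e is on some min-cut of G iff the min-cut
    weight of G - e equals mincut(G) - w(e).
    """
    if graph.n_vertices < 2:
        raise ValueError("need at least 2 vertices")
    G = _to_networkx(graph)
    if not nx.is_connected(G):
        raise ValueError("graph is disconnected; use connected components instead")
    base_cut, _ = nx.stoer_wagner(G)
    out: set[tuple[int, int]] = set()
    for i, j, w in sorted(graph.edges()):
        H = G.copy()
        H.remove_edge(i, j)
        if not nx.is_connected(H):
            reduced = 0.0
        else:
            reduced, _ = nx.stoer_wagner(H)
        if abs(reduced - (base_cut - w)) <= 1e-9 * max(1.0, base_cut):
            out.add((min(i, j), max(i, j)))
    return out


def single_mincut_edges(graph: ProperClusterGraph) -> set[tuple[int, int]]:
    """The edges crossing one deterministic global minimum cut."""
    G = _to_networkx(graph)
    if not nx.is_connected(G):
        raise ValueError("graph is disconnected; use connected components instead")
    _, (side_a, side_b) = nx.stoer_wagner(G)
    in_a = set(side_a)
    return {
        (min(i, j), max(i, j))
        for i, j, _w in graph.edges()
        if (i in in_a) != (j in in_a)
    }


def mincut_partition(graph: ProperClusterGraph, mode: str = "all_mincuts") -> list[set[int]]:
    """Partition a connected graph by deleting min-cut edges and returning
    the resulting connected components."""
    if mode not in _MODES:
        raise ValueError(f"mode must be one of {_MODES}")
    removed = (
        edges_on_any_mincut(graph) if mode == "all_mincuts" else single_mincut_edges(graph)
    )
    G = _to_networkx(graph)
    G.remove_edges_from(removed)
    comps = [set(c) for c in nx.connected_components(G)]
    comps.sort(key=min)
    return comps


def mincut_supertree(
    problem_or_trees: SupertreeProblem | Sequence[RootedTree],
    weights: Optional[Sequence[float]] = None,
    strategy: str | WeightingStrategy = "unit",
    seed: int = 0,
    mode: str = "all_mincuts",
) -> RootedTree:
    """Min-Cut Supertree over rooted source trees.

    Contraction eligibility always follows the original unit-weight rule
    (the pair is a proper cluster of every source tree) even when cut
    weights use the depth or branch-length strategy.
    """
    if mode not in _MODES:
        raise ValueError(f"mode must be one of {_MODES}")
    if isinstance(problem_or_trees, SupertreeProblem):
        problem = problem_or_trees
    else:
        problem = SupertreeProblem.from_trees(problem_or_trees, weights, strategy, seed)

    def splitter(graph: ProperClusterGraph, _seq) -> list[set[int]]:
        return mincut_partition(graph, mode=mode)

    def contraction_rule(trees, graph):
        return original_contraction_edges(trees, graph)

    return _solve(problem, splitter, contraction_rule)
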