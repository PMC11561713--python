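"""The Spectral Cluster Supertree recursion.

Given a multiset of rooted source trees whose taxon sets overlap, the
method recursively partitions the union of taxa: build the weighted proper
cluster graph, contract edges every relevant source tree agrees on, then
split — into connected components when the graph is disconnected, or
across the normalized-cut bottleneck via spectral clustering when it is
not.  Source trees are induced onto each block and the recursion's results
are joined under a new root.  Recursion stops at problems of one or two
taxa, or as soon as a single source tree spans the whole subproblem (it is
grafted in unchanged).

The recursion is driven iteratively with an explicit work stack so that
inputs with tens of thousands of taxa do not hit interpreter call-depth
limits.  Randomness (the k-means restarts inside spectral clustering) is
threaded through a ``numpy`` SeedSequence: every recursive branch derives
its own child sequence, so runs are reproducible and branches are
decorrelated.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

from .graph import (
    ProperClusterGraph,
    WeightingStrategy,
    build_graph,
    contract,
    contraction_edges,
)
from .partition import connected_components, spectral_bipartition
from .tree import RootedTree, TreeNode, leaf, merge_subtrees

__all__ = ["SupertreeProblem", "spectral_cluster_supertree", "construct_supertree"]

logger = logging.getLogger(__name__)


@dataclass
class SupertreeProblem:
    """One node of the divide-and-conquer recursion."""

    trees: list[RootedTree]
    weights: list[float]
    strategy: WeightingStrategy
    taxa: frozenset[str]
    seed_seq: np.random.SeedSequence
    depth: int = 0

    @classmethod
    def from_trees(
        cls,
        trees: Sequence[RootedTree],
        weights: Optional[Sequence[float]] = None,
        strategy: WeightingStrategy | str = "unit",
        seed: int = 0,
    ) -> "SupertreeProblem":
        if not trees:
            raise ValueError("at least one source tree is required")
        if isinstance(strategy, str):
            strategy = WeightingStrategy(kind=strategy)
        ws = strategy.weights_for(len(trees)) if weights is None else [float(w) for w in weights]
        if len(ws) != len(trees):
            raise ValueError(f"{len(ws)} weights for {len(trees)} trees")
        if any(w <= 0 for w in ws):
            raise ValueError("tree weights must be positive")
        taxa = frozenset().union(*(t.taxa for t in trees))
        return cls(
            trees=list(trees),
            weights=ws,
            strategy=strategy,
            taxa=taxa,
            seed_seq=np.random.SeedSequence(seed),
        )


# A splitter maps (contracted graph, seed sequence) -> list of vertex-index
# sets partitioning the graph's vertices; it is only consulted when the
# contracted graph is connected.
Splitter = Callable[[ProperClusterGraph, np.random.SeedSequence], list[set[int]]]


def _spectral_splitter(
    graph: ProperClusterGraph, seed_seq: np.random.SeedSequence
) -> list[set[int]]:
    seed = int(seed_seq.generate_state(1)[0] % (2**31))
    split = spectral_bipartition(graph, seed=seed)
    return [set(split.block_a), set(split.block_b)]


def _trivial_tree(taxa: Sequence[str]) -> RootedTree:
    if len(taxa) == 1:
        return leaf(taxa[0])
    root = TreeNode(children=[TreeNode(label=t) for t in sorted(taxa)])
    return RootedTree(root, validate=False)


@dataclass
class _Frame:
    problem: SupertreeProblem
    children: Optional[list[SupertreeProblem]] = None
    results: list[RootedTree] = field(default_factory=list)


def _solve(
    problem: SupertreeProblem,
    splitter: Splitter,
    contraction_rule: Callable[
        [Sequence[RootedTree], ProperClusterGraph], set[tuple[int, int]]
    ],
) -> RootedTree:
    stack = [_Frame(problem)]
    final: Optional[RootedTree] = None
    while stack:
        frame = stack[-1]
        if frame.children is None:
            step = _step(frame.problem, splitter, contraction_rule)
            if isinstance(step, RootedTree):
                stack.pop()
                if stack:
                    stack[-1].results.append(step)
                else:
                    final = step
                continue
            frame.children = step
        if len(frame.results) < len(frame.children):
            stack.append(_Frame(frame.children[len(frame.results)]))
            continue
        merged = merge_subtrees(frame.results)
        stack.pop()
        if stack:
            stack[-1].results.append(merged)
        else:
            final = merged
    assert final is not None
    return final


def _step(
    problem: SupertreeProblem,
    splitter: Splitter,
    contraction_rule: Callable[
        [Sequence[RootedTree], ProperClusterGraph], set[tuple[int, int]]
    ],
) -> RootedTree | list[SupertreeProblem]:
    taxa_sorted = sorted(problem.taxa)
    if len(taxa_sorted) <= 2:
        return _trivial_tree(taxa_sorted)
    if len(problem.trees) == 1 and problem.trees[0].taxa == problem.taxa:
        # single remaining source tree: graft it in unchanged
        return problem.trees[0]
    if not problem.trees:
        # only isolated taxa left: star under a common root
        return _trivial_star(taxa_sorted)
    graph = build_graph(problem.trees, problem.strategy, vertices=taxa_sorted)
    edges = contraction_rule(problem.trees, graph)
    contracted = contract(graph, edges)
    components = connected_components(contracted)
    if len(components) == 1:
        components = splitter(contracted, problem.seed_seq)
    blocks = [
        sorted(set().union(*(contracted.groups[v] for v in comp)))
        for comp in components
    ]
    blocks.sort(key=lambda b: b[0])
    logger.debug(
        "depth=%d taxa=%d trees=%d -> %d block(s)",
        problem.depth,
        len(taxa_sorted),
        len(problem.trees),
        len(blocks),
    )
    child_seqs = problem.seed_seq.spawn(len(blocks))
    children = []
    for block, seq in zip(blocks, child_seqs):
        block_set = frozenset(block)
        sub_trees: list[RootedTree] = []
        sub_weights: list[float] = []
        for tree, w in zip(problem.trees, problem.weights):
            induced = tree.induce(block_set)
            if induced is not None and induced.n_taxa >= 2:
                sub_trees.append(induced)
                sub_weights.append(w)
        children.append(
            SupertreeProblem(
                trees=sub_trees,
                weights=sub_weights,
                strategy=problem.strategy,
                taxa=block_set,
                seed_seq=seq,
                depth=problem.depth + 1,
            )
        )
    return children


def _trivial_star(taxa_sorted: Sequence[str]) -> RootedTree:
    root = TreeNode(children=[TreeNode(label=t) for t in taxa_sorted])
    return RootedTree(root, validate=False)


def spectral_cluster_supertree(problem: SupertreeProblem) -> RootedTree:
    """Run the Spectral Cluster Supertree recursion on ``problem``."""
    return _solve(problem, _spectral_splitter, contraction_edges)


def construct_supertree(
    trees: Sequence[RootedTree],
    weights: Optional[Sequence[float]] = None,
    strategy: str | WeightingStrategy = "unit",
    seed: int = 0,
) -> RootedTree:
    """Merge rooted source trees into a supertree with Spectral Cluster
    Supertree.

    Parameters
    ----------
    trees:
        Rooted source trees; leaf sets may differ but must overlap enough
        for the result to be informative.
    weights:
        Optional positive per-tree confidence weights (default all 1).
    strategy:
        ``"unit"``, ``"depth"`` or ``"branch_length"`` edge weighting for
        the proper cluster graph.
    seed:
        Master seed for the spectral clustering restarts.
    """
    problem = SupertreeProblem.from_trees(trees, weights, strategy, seed)
    return spectral_cluster_supertree(problem)
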