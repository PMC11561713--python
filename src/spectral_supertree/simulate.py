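"""Synthetic benchmark generation for the exact-recovery protocol.

The pipeline emulates a divide-and-conquer setting: a birth-death model
tree is simulated (birth rate 1.0, death rate 0.2 by default), rescaled so
every tip sits at distance 1 from the root, and its branch lengths are
then multiplied by a scaling factor that evolves from the root towards the
tips by Gaussian increments (sd 0.05, clamped to [0.05, 8.0]).  A
DCM3-style centroid-edge decomposition partitions the taxa into bounded,
overlapping subsets, and inducing the model tree on each subset yields a
collection of compatible source trees from which any sound supertree
method should reconstruct the model tree exactly.

``perturb_tree`` applies random nearest-neighbour-interchange moves to a
tree; it is a deliberately simple stand-in for topology-estimation error
when graded (conflicting) inputs are wanted.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from dendropy.simulate import treesim

from .tree import (
    RootedTree,
    TreeNode,
    _from_dendropy,
    _suppress_unary,
)

__all__ = [
    "BirthDeathConfig",
    "ScalingConfig",
    "DecompositionPlan",
    "simulate_model_tree",
    "decompose_taxa",
    "make_exact_dataset",
    "perturb_tree",
]


@dataclass(frozen=True)
class BirthDeathConfig:
    """Constant-rate birth-death simulation conditioned on the number of
    extant tips (extinct simulations are redrawn)."""

    n_taxa: int
    birth_rate: float = 1.0
    death_rate: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_taxa < 3:
            raise ValueError("need at least 3 taxa")
        if not self.birth_rate > self.death_rate >= 0:
            raise ValueError("require birth_rate > death_rate >= 0")


@dataclass(frozen=True)
class ScalingConfig:
    """Branch-rate evolution: the scaling factor starts at ``root_factor``
    and performs a clamped Gaussian walk down the tree; each node's factor
    multiplies its subtending branch."""

    root_factor: float = 1.0
    step_sd: float = 0.05
    lo: float = 0.05
    hi: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.lo <= self.root_factor <= self.hi):
            raise ValueError("require 0 < lo <= root_factor <= hi")
        if self.step_sd < 0:
            raise ValueError("step_sd must be non-negative")


@dataclass(frozen=True)
class DecompositionPlan:
    """Overlapping taxon subsets covering a model tree's leaves."""

    subsets: tuple[frozenset[str], ...]
    max_size: int

    def __post_init__(self) -> None:
        if any(len(s) > self.max_size for s in self.subsets):
            raise ValueError("subset exceeds max_size")
        if any(not s for s in self.subsets):
            raise ValueError("empty subset")

    @property
    def all_taxa(self) -> frozenset[str]:
        return frozenset().union(*self.subsets)

    def overlap_graph_connected(self) -> bool:
        n = len(self.subsets)
        if n <= 1:
            return True
        seen = {0}
        frontier = [0]
        while frontier:
            i = frontier.pop()
            for j in range(n):
                if j not in seen and self.subsets[i] & self.subsets[j]:
                    seen.add(j)
                    frontier.append(j)
        return len(seen) == n


# ---------------------------------------------------------------------------
# Model tree simulation
# ---------------------------------------------------------------------------


def simulate_model_tree(bd: BirthDeathConfig, sc: Optional[ScalingConfig] = None) -> RootedTree:
    """Simulate a rooted bifurcating model tree.

    The birth-death tree is rescaled to unit root-to-tip depth (it is
    ultrametric by construction), leaves are relabelled ``t0001``... in
    canonical traversal order, and branch-rate evolution is applied when a
    scaling configuration is given.  Deterministic per (bd.seed, sc.seed).
    """
    rng = random.Random(bd.seed)
    dtree = treesim.birth_death_tree(
        birth_rate=bd.birth_rate,
        death_rate=bd.death_rate,
        num_extant_tips=bd.n_taxa,
        rng=rng,
        repeat_until_success=True,
    )
    root = _from_dendropy(dtree.seed_node)
    root = _suppress_unary(root)
    root.length = None
    tree = RootedTree(root, validate=False)
    _relabel_leaves(tree)
    _normalise_depth(tree)
    if sc is not None and sc.step_sd >= 0:
        _evolve_branch_rates(tree, sc)
    return tree


def _relabel_leaves(tree: RootedTree) -> None:
    # canonical order: current (dendropy) labels sorted by (length, label)
    # would be unstable; instead sort leaves by their existing labels'
    # numeric suffix when present, falling back to string order
    leaves = list(tree.iter_leaves())

    def sort_key(node: TreeNode):
        label = node.label or ""
        digits = "".join(ch for ch in label if ch.isdigit())
        return (int(digits) if digits else 0, label)

    leaves.sort(key=sort_key)
    width = max(4, len(str(len(leaves))))
    for i, node in enumerate(leaves, start=1):
        node.label = f"t{i:0{width}d}"
    tree._index()


def _normalise_depth(tree: RootedTree) -> None:
    depths = [tree.node_root_length(lf) for lf in tree.iter_leaves()]
    span = max(depths)
    if span <= 0:
        raise ValueError("degenerate simulated tree with zero depth")
    if max(depths) - min(depths) > 1e-6 * span:
        raise AssertionError("birth-death tree is not ultrametric")
    for node in tree.iter_nodes():
        if node is not tree.root and node.length is not None:
            node.length = node.length / span


def _min_labels(tree: RootedTree) -> dict[int, str]:
    out: dict[int, str] = {}
    for node in tree.iter_postorder():
        if node.is_leaf:
            out[id(node)] = node.label  # type: ignore[assignment]
        else:
            out[id(node)] = min(out[id(c)] for c in node.children)
    return out


def _evolve_branch_rates(tree: RootedTree, sc: ScalingConfig) -> None:
    rng = np.random.default_rng(sc.seed)
    min_label = _min_labels(tree)
    stack: list[tuple[TreeNode, float]] = [(tree.root, sc.root_factor)]
    while stack:
        node, factor = stack.pop()
        # deterministic draw order: canonical child order, last pushed first
        ordered = sorted(node.children, key=lambda c: min_label[id(c)])
        for child in reversed(ordered):
            f = factor + float(rng.normal(0.0, sc.step_sd)) if sc.step_sd > 0 else factor
            f = min(max(f, sc.lo), sc.hi)
            if child.length is not None:
                child.length = child.length * f
            stack.append((child, f))


# ---------------------------------------------------------------------------
# DCM3-style decomposition
# ---------------------------------------------------------------------------


def _distances_from(tree: RootedTree, start: TreeNode) -> dict[int, float]:
    """Undirected branch-length distances from ``start`` to every node."""
    dist = {id(start): 0.0}
    frontier = [start]
    while frontier:
        node = frontier.pop()
        d = dist[id(node)]
        neighbours = []
        for child in node.children:
            neighbours.append((child, child.length or 0.0))
        if node.parent is not None:
            neighbours.append((node.parent, node.length or 0.0))
        for nbr, w in neighbours:
            if id(nbr) not in dist:
                dist[id(nbr)] = d + w
                frontier.append(nbr)
    return dist


def _centroid_node(tree: RootedTree) -> TreeNode:
    """The non-root node whose subtending edge best balances leaf counts
    (ties by smallest descendant leaf label)."""
    sets = tree.leaf_sets()
    n = tree.n_taxa
    best: tuple[int, str] | None = None
    best_node: TreeNode | None = None
    for node in tree.iter_nodes():
        if node is tree.root:
            continue
        c = len(sets[id(node)])
        key = (max(c, n - c), min(sets[id(node)]))
        if best is None or key < best:
            best = key
            best_node = node
    assert best_node is not None
    return best_node


def _directions_below(sub: RootedTree, v: TreeNode) -> list[frozenset[str]]:
    """Leaf sets of the subtrees hanging below the centroid edge: one per
    child of its lower endpoint."""
    if v.is_leaf:
        return [frozenset((v.label,))]  # type: ignore[arg-type]
    sets = sub.leaf_sets()
    return [sets[id(c)] for c in v.children]


def _directions_above(sub: RootedTree, v: TreeNode) -> list[frozenset[str]]:
    """Leaf sets of the subtrees hanging off the path from the centroid
    edge's upper endpoint to the root: one per off-path child."""
    path: list[TreeNode] = []
    node = v.parent
    while node is not None:
        path.append(node)
        node = node.parent
    on_path = {id(n) for n in path} | {id(v)}
    sets = sub.leaf_sets()
    return [
        sets[id(c)]
        for a in path
        for c in a.children
        if id(c) not in on_path
    ]


def _short_subtree_separator(
    sub: RootedTree,
    directions: list[frozenset[str]],
    dist: dict[int, float],
    k: int,
) -> list[str]:
    """Up to ``k`` separator taxa spread over the subtrees around the
    centroid edge: the nearest leaf of each direction first (directions
    ordered by proximity), then second-nearest, round-robin, until the
    budget is filled.  Ties break lexicographically."""

    def leaf_key(taxon: str) -> tuple[float, str]:
        return (dist[id(sub.leaf_node(taxon))], taxon)

    ranked = [sorted(d, key=leaf_key) for d in directions]
    ranked.sort(key=lambda r: leaf_key(r[0]))
    out: list[str] = []
    rank = 0
    while len(out) < k:
        progressed = False
        for r in ranked:
            if rank < len(r):
                progressed = True
                out.append(r[rank])
                if len(out) == k:
                    break
        if not progressed:
            break
        rank += 1
    return out


def decompose_taxa(
    tree: RootedTree, max_size: int, seed: int = 0, overlap: int = 4
) -> DecompositionPlan:
    """Recursive centroid-edge decomposition into overlapping subsets.

    While a part exceeds ``max_size``, the induced tree is split at its
    centroid edge (the edge best balancing leaf counts).  Each side keeps
    its own leaves plus a *short-subtree separator* from the opposite
    side: up to ``overlap`` leaves chosen nearest-first but spread across
    the distinct subtrees hanging off the centroid edge, so the separator
    orients the boundary in every direction rather than sampling a single
    nearby branch.  Adjacent parts always share separator taxa, making the
    final subset overlap graph connected by construction.

    ``seed`` is accepted for interface uniformity; the decomposition is
    fully deterministic (ties are broken lexicographically).
    """
    if max_size < 4:
        raise ValueError("max_size must be at least 4")
    if not tree.has_branch_lengths:
        raise ValueError("decomposition requires branch lengths (nearest-leaf separators)")
    subsets: list[frozenset[str]] = []

    def recurse(sub: RootedTree) -> None:
        n = sub.n_taxa
        if n <= max_size:
            subsets.append(frozenset(sub.taxa))
            return
        v = _centroid_node(sub)
        side1 = sub.leaf_sets()[id(v)]
        side2 = frozenset(sub.taxa) - side1
        # cap separators so neither child equals the full leaf set
        k1 = min(overlap, len(side1), n - len(side2) - 1)
        k2 = min(overlap, len(side2), n - len(side1) - 1)
        d_below = _distances_from(sub, v)
        d_above = _distances_from(sub, v.parent if v.parent is not None else v)
        sep1 = _short_subtree_separator(sub, _directions_below(sub, v), d_below, k1)
        sep2 = _short_subtree_separator(sub, _directions_above(sub, v), d_above, k2)
        recurse(sub.induce(side1 | frozenset(sep2)))  # type: ignore[arg-type]
        recurse(sub.induce(side2 | frozenset(sep1)))  # type: ignore[arg-type]

    recurse(tree)
    # de-duplicate while keeping deterministic order
    unique = sorted(set(subsets), key=lambda s: sorted(s))
    plan = DecompositionPlan(tuple(unique), max_size=max_size)
    if plan.all_taxa != tree.taxa:
        raise AssertionError("decomposition lost taxa")
    if not plan.overlap_graph_connected():  # pragma: no cover - safety net
        plan = _bridge_components(plan)
    return plan


def _bridge_components(plan: DecompositionPlan) -> DecompositionPlan:
    """Connect a disconnected subset-overlap graph with small bridge
    subsets (two taxa from each side).  Safety net; the recursive
    decomposition produces connected plans by construction."""
    subsets = list(plan.subsets)
    while True:
        comp = _overlap_components(subsets)
        if len(comp) == 1:
            break
        first, second = comp[0], comp[1]
        bridge = frozenset(
            sorted(subsets[first[0]])[:2] + sorted(subsets[second[0]])[:2]
        )
        subsets.append(bridge)
    return DecompositionPlan(tuple(subsets), max_size=plan.max_size)


def _overlap_components(subsets: list[frozenset[str]]) -> list[list[int]]:
    n = len(subsets)
    seen: set[int] = set()
    comps: list[list[int]] = []
    for start in range(n):
        if start in seen:
            continue
        comp = [start]
        seen.add(start)
        frontier = [start]
        while frontier:
            i = frontier.pop()
            for j in range(n):
                if j not in seen and subsets[i] & subsets[j]:
                    seen.add(j)
                    comp.append(j)
                    frontier.append(j)
        comps.append(sorted(comp))
    return comps


def make_exact_dataset(tree: RootedTree, plan: DecompositionPlan) -> list[RootedTree]:
    """Induce the model tree on each subset of the plan: a collection of
    compatible source trees displayed by the model tree."""
    if not plan.all_taxa <= tree.taxa:
        raise ValueError("plan references taxa absent from the tree")
    out = []
    for subset in plan.subsets:
        induced = tree.induce(subset)
        assert induced is not None
        out.append(induced)
    return out


# ---------------------------------------------------------------------------
# Topology perturbation
# ---------------------------------------------------------------------------


def perturb_tree(tree: RootedTree, n_moves: int, seed: int = 0) -> RootedTree:
    """Apply ``n_moves`` random rooted nearest-neighbour-interchange moves.

    Each move picks an internal non-root node v and swaps one of its
    children with one of its siblings.  The leaf set is unchanged; branch
    lengths travel with their subtrees.
    """
    if n_moves < 0:
        raise ValueError("n_moves must be non-negative")
    result = tree.copy()
    if n_moves == 0:
        return result
    rng = np.random.default_rng(seed)
    for _ in range(n_moves):
        candidates = [
            node
            for node in result.iter_nodes()
            if node is not result.root and not node.is_leaf
        ]
        if not candidates:
            break
        # deterministic candidate order for reproducibility
        candidates.sort(key=lambda nd: min(lf.label for lf in _leaves_under(nd)))
        v = candidates[rng.integers(len(candidates))]
        u = v.parent
        assert u is not None
        siblings = [c for c in u.children if c is not v]
        child = v.children[rng.integers(len(v.children))]
        sib = siblings[rng.integers(len(siblings))]
        # swap
        v.children[v.children.index(child)] = sib
        u.children[u.children.index(sib)] = child
        sib.parent = v
        child.parent = u
    return RootedTree(result.root, validate=False)


def _leaves_under(node: TreeNode):
    stack = [node]
    while stack:
        nd = stack.pop()
        if nd.is_leaf:
            yield nd
        else:
            stack.extend(nd.children)
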