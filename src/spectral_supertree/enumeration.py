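"""Exhaustive enumeration of rooted bifurcating topologies (test oracle).

There are (2n-3)!! distinct rooted bifurcating trees on n labelled taxa
(1, 3, 15, 105, 945 for n = 2..6); they are generated by inserting each
successive taxon on every edge of every smaller tree, including above the
root.
"""

from __future__ import annotations

from typing import Iterable, Sequence

from .tree import RootedTree, TreeNode

__all__ = ["enumerate_rooted_bifurcating_trees"]

_MAX_TAXA = 7

# nested-tuple representation: a leaf is a label string, an internal node a
# 2-tuple of subtrees
_Rep = "str | tuple"


def _insert_everywhere(rep, taxon: str) -> Iterable[tuple]:
    yield (rep, taxon)  # new node above this subtree (above the root at top level)
    if isinstance(rep, tuple):
        left, right = rep
        for new_left in _insert_everywhere(left, taxon):
            yield (new_left, right)
        for new_right in _insert_everywhere(right, taxon):
            yield (left, new_right)


def _to_tree(rep) -> RootedTree:
    def build(r) -> TreeNode:
        if isinstance(r, str):
            return TreeNode(label=r)
        return TreeNode(children=[build(r[0]), build(r[1])])

    return RootedTree(build(rep), validate=False)


def enumerate_rooted_bifurcating_trees(taxa: Sequence[str]) -> list[RootedTree]:
    """All distinct rooted bifurcating topologies on the given taxa."""
    labels = sorted(set(taxa))
    if len(labels) != len(list(taxa)):
        raise ValueError("taxa must be unique")
    if not 2 <= len(labels) <= _MAX_TAXA:
        raise ValueError(f"supported for 2..{_MAX_TAXA} taxa")
    reps: list = [(labels[0], labels[1])]
    for taxon in labels[2:]:
        reps = [new for rep in reps for new in _insert_everywhere(rep, taxon)]
    return [_to_tree(rep) for rep in reps]
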