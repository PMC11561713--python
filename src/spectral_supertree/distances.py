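"""Rooted tree comparison metrics.

All metrics operate on the *non-trivial* clades of the two trees (clades
that are neither singletons nor the full leaf set; trivial clades are
shared whenever the leaf sets agree, so they cancel in every symmetric
difference).

* clade Robinson-Foulds: |C(T1) xor C(T2)|, equivalently FP + FN of the
  clade confusion counts;
* rooted F1 = 2TP / (2TP + FP + FN), with the identities
  RF = 2 TP (1/F1 - 1) (TP > 0) and, for fully resolved n-taxon trees,
  RF = 2 (n - 2) (1 - F1);
* Matching Cluster distance: minimum-weight perfect matching between the
  clade lists (the shorter list padded with empty sets), edge weight =
  symmetric-difference cardinality.  Unlike RF it degrades gradually as
  clades become *similar* rather than identical.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment

from .tree import RootedTree

__all__ = [
    "CladeConfusion",
    "clade_confusion",
    "f1_score",
    "rooted_rf",
    "matching_cluster_distance",
]


@dataclass(frozen=True)
class CladeConfusion:
    """Clade-level confusion counts between a model tree and a supertree.

    tp: clades present in both; fp: in the supertree only; fn: in the
    model tree only.
    """

    tp: int
    fp: int
    fn: int


def _check_same_taxa(t1: RootedTree, t2: RootedTree) -> None:
    if t1.taxa != t2.taxa:
        extra = sorted(t1.taxa ^ t2.taxa)[:5]
        raise ValueError(f"trees have different leaf sets (e.g. {extra})")


def clade_confusion(model: RootedTree, supertree: RootedTree) -> CladeConfusion:
    """TP/FP/FN counts over non-trivial clades (identical leaf sets required)."""
    _check_same_taxa(model, supertree)
    cm = model.clade_set().clades
    cs = supertree.clade_set().clades
    return CladeConfusion(
        tp=len(cm & cs), fp=len(cs - cm), fn=len(cm - cs)
    )


def f1_score(conf: CladeConfusion) -> float:
    """Rooted clade F1; defined as 1.0 when both trees have no non-trivial
    clades (identical empty clade sets)."""
    denom = 2 * conf.tp + conf.fp + conf.fn
    if denom == 0:
        return 1.0
    return 2 * conf.tp / denom


def rooted_rf(t1: RootedTree, t2: RootedTree) -> int:
    """Clade Robinson-Foulds distance: |C(T1) xor C(T2)| over non-trivial
    clades."""
    _check_same_taxa(t1, t2)
    return len(t1.clade_set().clades ^ t2.clade_set().clades)


def _clade_matrix(
    clade_lists: list[frozenset[str]], taxon_index: dict[str, int]
) -> np.ndarray:
    A = np.zeros((len(clade_lists), len(taxon_index)), dtype=np.int64)
    for r, clade in enumerate(clade_lists):
        for t in clade:
            A[r, taxon_index[t]] = 1
    return A


def matching_cluster_distance(t1: RootedTree, t2: RootedTree) -> int:
    """Matching Cluster distance between two rooted trees on the same taxa.

    Builds the complete bipartite graph between the non-trivial clade
    lists (padded with empty sets to equal length), with edge weight the
    cardinality of the symmetric difference, and returns the total weight
    of a minimum-weight perfect matching.
    """
    _check_same_taxa(t1, t2)
    c1 = sorted(t1.clade_set().clades, key=lambda c: (len(c), sorted(c)))
    c2 = sorted(t2.clade_set().clades, key=lambda c: (len(c), sorted(c)))
    size = max(len(c1), len(c2))
    if size == 0:
        return 0
    taxa = sorted(t1.taxa)
    index = {t: i for i, t in enumerate(taxa)}
    # padded rows/columns are all-zero (empty sets): |empty ^ c| = |c|
    A1 = np.zeros((size, len(taxa)), dtype=np.int64)
    A2 = np.zeros((size, len(taxa)), dtype=np.int64)
    A1[: len(c1)] = _clade_matrix(c1, index)
    A2[: len(c2)] = _clade_matrix(c2, index)
    s1 = A1.sum(axis=1)
    s2 = A2.sum(axis=1)
    cost = s1[:, None] + s2[None, :] - 2 * (A1 @ A2.T)
    rows, cols = linear_sum_assignment(cost)
    return int(cost[rows, cols].sum())
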