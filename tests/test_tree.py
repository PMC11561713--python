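"""Rooted tree structure, Newick round-trips, clades and induced subtrees."""

from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from spectral_supertree import (
    NewickParseError,
    TreeValidationError,
    clades,
    induce_subtree,
    leaf,
    merge_subtrees,
    parse_newick,
)

from conftest import random_resolved_tree, random_tree_with_lengths


class TestParseNewick:
    def test_minimal_nesting(self):
        t = parse_newick("((a,b),c);")
        assert t.taxa == {"a", "b", "c"}
        kids = t.root.children
        assert len(kids) == 2

    def test_caterpillar_clades(self):
        t = parse_newick("(((a,b),c),d);")
        assert set(map(frozenset, t.clade_set())) == {
            frozenset("ab"),
            frozenset("abc"),
        }

    def test_branch_lengths_read_back(self):
        t = parse_newick("((a:1.0,b:2.0):0.5,c:3.0);")
        lengths = sorted(
            n.length for n in t.iter_nodes() if n is not t.root
        )
        assert lengths == [0.5, 1.0, 2.0, 3.0]

    def test_malformed_raises(self):
        with pytest.raises(NewickParseError):
            parse_newick("((a,b),c;")

    def test_duplicate_labels_rejected(self):
        with pytest.raises(TreeValidationError):
            parse_newick("((a,b),a);")

    def test_mixed_branch_lengths_rejected(self):
        with pytest.raises(TreeValidationError):
            parse_newick("((a:1.0,b),c:2.0);")

    def test_multifurcation_preserved(self):
        t = parse_newick("((a,b,c),d);")
        assert frozenset("abc") in t.clade_set().clades
        inner = t.lca_or_root("a", "b")
        assert len(inner.children) == 3

    def test_unary_chain_suppressed_and_lengths_summed(self):
        t = parse_newick("(((a:1.0):2.0,b:1.0):1.0,c:4.0);")
        node = t.leaf_node("a")
        assert node.length == pytest.approx(3.0)


class TestWriteNewick:
    def test_canonical_child_order(self):
        assert parse_newick("((b,a),c);").newick() == "((a,b),c);"
        assert parse_newick("(c,(b,a));").newick() == "((a,b),c);"

    def test_single_leaf(self):
        assert leaf("a").newick() == "a;"

    def test_round_trip_preserves_clades_and_lengths(self):
        rng = np.random.default_rng(42)
        labels = [f"s{i}" for i in range(50)]
        t = random_tree_with_lengths(labels, rng)
        t2 = parse_newick(t.newick())
        assert t2.clade_set(include_trivial=True).clades == t.clade_set(
            include_trivial=True
        ).clades
        assert t2.total_branch_length() == pytest.approx(
            t.total_branch_length(), abs=1e-12
        )


class TestCladeQueries:
    @pytest.mark.parametrize(
        "newick, expected",
        [
            ("(((a,b),c),d);", {frozenset("ab"), frozenset("abc")}),
            ("(a,((b,c),d));", {frozenset("bc"), frozenset("bcd")}),
            ("(a,b);", set()),
        ],
    )
    def test_nontrivial_clades(self, newick, expected):
        assert parse_newick(newick).clade_set().clades == frozenset(expected)

    def test_trivial_clade_count(self):
        rng = np.random.default_rng(1)
        t = random_resolved_tree([f"x{i}" for i in range(20)], rng)
        n_internal = sum(1 for n in t.iter_nodes() if not n.is_leaf)
        assert len(t.clade_set(include_trivial=True)) == n_internal + 20

    def test_laminarity(self):
        rng = np.random.default_rng(2)
        t = random_resolved_tree([f"x{i}" for i in range(15)], rng)
        cl = list(t.clade_set(include_trivial=True))
        for a, b in combinations(cl, 2):
            assert not (a & b) or a <= b or b <= a


class TestProperClusterAndLca:
    def test_cherry_under_nonroot(self):
        t = parse_newick("(((a,b),c),d);")
        assert t.is_proper_cluster("a", "b")
        assert not t.is_proper_cluster("a", "d")

    def test_balanced_four_taxa_brute_force(self):
        t = parse_newick("((a,b),(c,d));")
        proper = {
            frozenset(p)
            for p in combinations("abcd", 2)
            if t.is_proper_cluster(*p)
        }
        assert proper == {frozenset("ab"), frozenset("cd")}

    def test_absent_taxon_gives_root(self):
        t = parse_newick("(((a,b),c),d);")
        assert t.lca_or_root("a", "x") is t.root
        assert not t.is_proper_cluster("a", "x")

    def test_lca_matches_ancestor_intersection_oracle(self):
        rng = np.random.default_rng(3)
        t = random_resolved_tree([f"x{i}" for i in range(12)], rng)
        for u, v in combinations(sorted(t.taxa), 2):
            ancestors_u = t.ancestors(t.leaf_node(u))
            ancestors_v = {id(n) for n in t.ancestors(t.leaf_node(v))}
            oracle = next(n for n in ancestors_u if id(n) in ancestors_v)
            assert t.lca_or_root(u, v) is oracle

    def test_proper_cluster_iff_lca_below_root(self):
        rng = np.random.default_rng(4)
        t = random_resolved_tree([f"x{i}" for i in range(10)], rng)
        for u, v in combinations(sorted(t.taxa), 2):
            assert t.is_proper_cluster(u, v) == (
                t.lca_or_root(u, v) is not t.root
            )


class TestDepthAndRootLength:
    def test_root_values(self):
        t = parse_newick("((a:1.0,b:2.0):0.5,c:3.0);")
        assert t.node_depth(t.root) == 0
        assert t.node_root_length(t.root) == 0.0

    def test_internal_node(self):
        t = parse_newick("((a:1.0,b:2.0):0.5,c:3.0);")
        node = t.lca_or_root("a", "b")
        assert t.node_depth(node) == 1
        assert t.node_root_length(node) == pytest.approx(0.5)

    def test_depth_equals_ancestor_count(self):
        rng = np.random.default_rng(5)
        t = random_resolved_tree([f"x{i}" for i in range(20)], rng)
        for node in t.iter_nodes():
            assert t.node_depth(node) == len(t.ancestors(node)) - 1

    def test_missing_lengths_error(self):
        t = parse_newick("((a,b),c);")
        with pytest.raises(TreeValidationError, match="depth weighting"):
            t.node_root_length(t.leaf_node("a"))


class TestInduceSubtree:
    def test_identity(self):
        t = parse_newick("(((a,b),c),d);")
        assert induce_subtree(t, {"a", "b", "c", "d"}).newick() == t.newick()

    def test_deletion_with_suppression(self):
        t = parse_newick("(((a,b),c),d);")
        assert induce_subtree(t, {"a", "c", "d"}).newick() == "((a,c),d);"

    def test_disjoint_taxa_gives_none(self):
        t = parse_newick("(((a,b),c),d);")
        assert induce_subtree(t, {"x", "y"}) is None

    def test_idempotent(self):
        rng = np.random.default_rng(6)
        t = random_resolved_tree([f"x{i}" for i in range(16)], rng)
        taxa = set(sorted(t.taxa)[:7])
        once = induce_subtree(t, taxa)
        twice = induce_subtree(once, taxa)
        assert once.newick() == twice.newick()

    def test_suppressed_lengths_sum(self):
        t = parse_newick("(((a:1.0,b:1.0):2.0,c:1.5):0.5,d:4.0);")
        ind = induce_subtree(t, {"a", "d"})
        # path a->root collapses: 1.0 + 2.0 + 0.5 = 3.5
        assert ind.leaf_node("a").length == pytest.approx(3.5)


class TestMergeSubtrees:
    def test_two_leaves_make_cherry(self):
        assert merge_subtrees([leaf("a"), leaf("b")]).newick() == "(a,b);"

    def test_multifurcating_merge(self):
        parts = [parse_newick("(a,b);"), leaf("c"), parse_newick("(d,e);")]
        merged = merge_subtrees(parts)
        assert len(merged.root.children) == 3
        assert merged.newick() == "((a,b),c,(d,e));"

    def test_single_subtree_identity(self):
        t = parse_newick("((a,b),c);")
        assert merge_subtrees([t]) is t

    def test_overlapping_leaf_sets_rejected(self):
        with pytest.raises(ValueError):
            merge_subtrees([parse_newick("(a,b);"), parse_newick("(b,c);")])


@settings(derandomize=True, max_examples=30, deadline=None)
@given(st.integers(min_value=0, max_value=10_000), st.integers(min_value=3, max_value=40))
def test_round_trip_stability_property(seed, n):
    """parse(write(t)) reproduces clade set and branch lengths exactly."""
    rng = np.random.default_rng(seed)
    t = random_tree_with_lengths([f"x{i}" for i in range(n)], rng)
    t2 = parse_newick(t.newick())
    assert t2.clade_set().clades == t.clade_set().clades
    assert abs(t2.total_branch_length() - t.total_branch_length()) < 1e-9
    assert t2.newick() == t.newick()
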