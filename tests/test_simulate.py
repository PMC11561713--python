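"""Birth-death model trees, branch-rate evolution, centroid-edge
decomposition and the exact-recovery pipeline."""

import numpy as np
import pytest

from spectral_supertree import (
    BirthDeathConfig,
    ScalingConfig,
    construct_supertree,
    decompose_taxa,
    make_exact_dataset,
    matching_cluster_distance,
    perturb_tree,
    rooted_rf,
    simulate_model_tree,
)
from spectral_supertree.simulate import DecompositionPlan

from conftest import displays


class TestSimulateModelTree:
    def test_unit_depth_before_scaling(self):
        tree = simulate_model_tree(BirthDeathConfig(n_taxa=12, seed=1), sc=None)
        for lf in tree.iter_leaves():
            assert tree.node_root_length(lf) == pytest.approx(1.0, abs=1e-9)

    def test_zero_noise_keeps_ultrametric(self):
        tree = simulate_model_tree(
            BirthDeathConfig(n_taxa=10, seed=2),
            ScalingConfig(step_sd=0.0, seed=3),
        )
        for lf in tree.iter_leaves():
            assert tree.node_root_length(lf) == pytest.approx(1.0, abs=1e-9)

    def test_bifurcating_with_requested_taxa(self):
        tree = simulate_model_tree(BirthDeathConfig(n_taxa=30, seed=4), ScalingConfig(seed=5))
        assert tree.n_taxa == 30
        for node in tree.iter_nodes():
            if not node.is_leaf:
                assert len(node.children) == 2

    def test_deterministic_per_seed(self):
        a = simulate_model_tree(BirthDeathConfig(n_taxa=15, seed=6), ScalingConfig(seed=7))
        b = simulate_model_tree(BirthDeathConfig(n_taxa=15, seed=6), ScalingConfig(seed=7))
        c = simulate_model_tree(BirthDeathConfig(n_taxa=15, seed=8), ScalingConfig(seed=7))
        assert a.newick() == b.newick()
        assert a.newick() != c.newick()

    def test_scaling_factors_respect_bounds(self):
        # Monte-Carlo: even with a large step, scaled branch lengths never
        # exceed what the clamp bounds allow relative to the unscaled tree
        base = simulate_model_tree(BirthDeathConfig(n_taxa=100, seed=9), sc=None)
        base_lengths = {
            id(n): n.length for n in base.iter_nodes() if n is not base.root
        }
        for seed in range(30):
            scaled = simulate_model_tree(
                BirthDeathConfig(n_taxa=100, seed=9),
                ScalingConfig(step_sd=1.5, seed=seed),
            )
            base_iter = [n for n in base.iter_nodes() if n is not base.root]
            scaled_iter = [n for n in scaled.iter_nodes() if n is not scaled.root]
            for b_node, s_node in zip(base_iter, scaled_iter):
                b_len = base_lengths[id(b_node)]
                if b_len == 0:
                    assert s_node.length == 0
                else:
                    factor = s_node.length / b_len
                    assert 0.05 - 1e-9 <= factor <= 8.0 + 1e-9

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            BirthDeathConfig(n_taxa=2)
        with pytest.raises(ValueError):
            BirthDeathConfig(n_taxa=10, birth_rate=0.1, death_rate=0.2)
        with pytest.raises(ValueError):
            ScalingConfig(lo=0.5, root_factor=0.1)


class TestDecomposeTaxa:
    def test_small_tree_single_subset(self):
        tree = simulate_model_tree(BirthDeathConfig(n_taxa=8, seed=10), ScalingConfig(seed=11))
        plan = decompose_taxa(tree, max_size=8)
        assert plan.subsets == (frozenset(tree.taxa),)

    def test_split_respects_invariants(self):
        tree = simulate_model_tree(BirthDeathConfig(n_taxa=8, seed=12), ScalingConfig(seed=13))
        plan = decompose_taxa(tree, max_size=5)
        assert len(plan.subsets) >= 2
        assert all(len(s) <= 5 for s in plan.subsets)
        assert plan.all_taxa == tree.taxa
        assert plan.overlap_graph_connected()

    def test_large_tree_invariant_suite(self):
        tree = simulate_model_tree(BirthDeathConfig(n_taxa=500, seed=14), ScalingConfig(seed=15))
        plan = decompose_taxa(tree, max_size=50)
        assert all(4 <= len(s) <= 50 for s in plan.subsets)
        assert plan.all_taxa == tree.taxa
        assert plan.overlap_graph_connected()

    def test_requires_branch_lengths(self):
        from spectral_supertree import parse_newick

        with pytest.raises(ValueError, match="branch lengths"):
            decompose_taxa(parse_newick("((a,b),(c,d));"), max_size=4)

    def test_deterministic(self):
        tree = simulate_model_tree(BirthDeathConfig(n_taxa=60, seed=16), ScalingConfig(seed=17))
        assert decompose_taxa(tree, max_size=20) == decompose_taxa(tree, max_size=20)


class TestMakeExactDataset:
    def test_full_subset_returns_model(self):
        tree = simulate_model_tree(BirthDeathConfig(n_taxa=10, seed=18), ScalingConfig(seed=19))
        plan = DecompositionPlan((frozenset(tree.taxa),), max_size=10)
        (only,) = make_exact_dataset(tree, plan)
        assert only.newick() == tree.newick()

    def test_manual_induction(self):
        from spectral_supertree import parse_newick

        tree = parse_newick("(((a,b),c),d);")
        plan = DecompositionPlan(
            (frozenset("abc"), frozenset("bcd")), max_size=3
        )
        sources = make_exact_dataset(tree, plan)
        assert sorted(s.newick() for s in sources) == ["((a,b),c);", "((b,c),d);"]

    def test_all_sources_displayed_by_model(self):
        tree = simulate_model_tree(BirthDeathConfig(n_taxa=80, seed=20), ScalingConfig(seed=21))
        plan = decompose_taxa(tree, max_size=25)
        for source in make_exact_dataset(tree, plan):
            assert displays(tree, source)


class TestPerturbTree:
    def test_zero_moves_is_identity(self):
        tree = simulate_model_tree(BirthDeathConfig(n_taxa=20, seed=22), ScalingConfig(seed=23))
        assert perturb_tree(tree, 0, seed=1).newick() == tree.newick()

    def test_single_nni_on_caterpillar(self):
        from spectral_supertree import parse_newick

        # enumerating the NNI neighbourhood of the 4-leaf caterpillar shows
        # every single interchange replaces exactly one non-trivial clade
        base = parse_newick("(((a,b),c),d);")
        seen = set()
        for seed in range(20):
            moved = perturb_tree(base, 1, seed=seed)
            seen.add(rooted_rf(base, moved))
        assert seen == {2}

    def test_leaf_set_conserved(self):
        tree = simulate_model_tree(BirthDeathConfig(n_taxa=25, seed=24), ScalingConfig(seed=25))
        for seed in range(20):
            assert perturb_tree(tree, 5, seed=seed).taxa == tree.taxa


class TestEndToEnd:
    def test_exact_pipeline_recovers_model(self):
        model = simulate_model_tree(BirthDeathConfig(n_taxa=100, seed=26), ScalingConfig(seed=27))
        plan = decompose_taxa(model, max_size=30)
        sources = make_exact_dataset(model, plan)
        out = construct_supertree(sources, strategy="branch_length", seed=26)
        assert rooted_rf(model, out) == 0
        assert matching_cluster_distance(model, out) == 0

    def test_noise_degrades_gradually(self):
        # mean Matching Cluster distance to the model is non-decreasing in
        # the number of NNI perturbations applied to each source tree
        model = simulate_model_tree(BirthDeathConfig(n_taxa=40, seed=28), ScalingConfig(seed=29))
        plan = decompose_taxa(model, max_size=15)
        sources = make_exact_dataset(model, plan)
        means = []
        for m in (0, 2, 6):
            vals = []
            for rep in range(8):
                noisy = [
                    perturb_tree(s, m, seed=rep * 100 + k)
                    for k, s in enumerate(sources)
                ]
                out = construct_supertree(noisy, seed=rep)
                vals.append(matching_cluster_distance(model, out))
            means.append(np.mean(vals))
        assert means[0] == 0.0
        assert means[0] <= means[1] <= means[2] + 1e-9
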