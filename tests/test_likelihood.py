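import math

import numpy as np
import pytest
from scipy.integrate import quad

from imcoal import (
    GeneTree,
    IMParams,
    LociLikelihood,
    build_schedule,
    gene_tree_log_density,
    loci_log_likelihood,
    migration_generator,
)

from conftest import four_tip_tree, two_tip_tree


class TestClosedForms:
    """Spot checks against hand-derived densities for degenerate cases."""

    def test_cross_population_pair_no_migration(self):
        # pair must wait for the split, then coalesce at rate 2/theta3
        p = IMParams(10, 10, 10, 0, 0, 10)
        tree = two_tip_tree(15.0, pops=(1, 2))
        assert math.exp(gene_tree_log_density(tree, p)) == pytest.approx(
            0.2 * math.exp(-1.0), abs=1e-8
        )

    def test_same_population_pair_no_migration(self):
        p = IMParams(10, 10, 10, 0, 0, 10)
        tree = two_tip_tree(3.0, pops=(1, 1))
        assert math.exp(gene_tree_log_density(tree, p)) == pytest.approx(
            0.2 * math.exp(-0.6), abs=1e-8
        )

    def test_kingman_four_tips(self):
        # tau = 0: pure single-population coalescent with theta3
        p = IMParams(10, 10, 10, 0, 0, 0)
        tree = four_tip_tree(1.0, 2.0, 3.0)
        expected = -2.0 + 3.0 * math.log(0.2)
        assert gene_tree_log_density(tree, p) == pytest.approx(expected, abs=1e-8)

    def test_impossible_history_is_minus_inf(self):
        p = IMParams(10, 10, 10, 0, 0, 10)
        tree = two_tip_tree(5.0, pops=(1, 2))  # coalesces before the split
        assert gene_tree_log_density(tree, p) == -math.inf


class TestMigrationGenerator:
    def test_no_migration_is_diagonal(self):
        p = IMParams(10, 10, 10, 0, 0, 5)
        Q = migration_generator(2, p)
        assert np.allclose(Q, np.diag(np.diag(Q)))
        # mask 0 = both lineages in population 1: hazard k(k-1)/theta1
        assert Q[0, 0] == pytest.approx(-0.2, abs=1e-12)
        # mask 3 = both in population 2
        assert Q[3, 3] == pytest.approx(-0.2, abs=1e-12)
        # split pair: no coalescence possible
        assert Q[1, 1] == Q[2, 2] == 0.0

    def test_single_lineage_two_state_chain(self):
        p = IMParams(10, 10, 10, 0.1, 0.0, 5)
        Q = migration_generator(1, p)
        assert Q == pytest.approx(np.array([[-0.1, 0.1], [0.0, 0.0]]), abs=1e-12)

    def test_row_sums_equal_minus_coalescent_hazard(self):
        p = IMParams(8, 12, 10, 0.07, 0.03, 5)
        k = 3
        Q = migration_generator(k, p)
        masks = np.arange(2**k)
        n2 = np.array([bin(m).count("1") for m in masks])
        n1 = k - n2
        coal = n1 * (n1 - 1) / p.theta1 + n2 * (n2 - 1) / p.theta2
        assert Q.sum(axis=1) == pytest.approx(-coal, abs=1e-12)


class TestDensityProperties:
    def test_normalizes_over_coalescence_time(self):
        """2-tip densities integrate to 1 over (0, inf), split at tau."""
        p = IMParams(10, 10, 10, 0.1, 0.0, 10)
        for pops in [(1, 2), (1, 1), (2, 2)]:
            f = lambda t: math.exp(gene_tree_log_density(two_tip_tree(t, pops), p))
            head, _ = quad(f, 0, p.tau, limit=200)
            tail, _ = quad(f, p.tau, np.inf, limit=200)
            assert head + tail == pytest.approx(1.0, abs=1e-6)

    def test_continuous_at_zero_migration(self):
        """m -> 0 recovers the no-migration likelihood (for trees possible at m = 0)."""
        from imcoal import SimulationConfig, sample_blocks, simulate_loci

        loci = simulate_loci(
            SimulationConfig(params=IMParams(10, 10, 10, 0, 0, 10), rho=0.0),
            50,
            seed=77,
        )
        trees = sample_blocks(loci, seed=78)
        p0 = IMParams(10, 10, 10, 0, 0, 10)
        p_eps = IMParams(10, 10, 10, 1e-12, 1e-12, 10)
        a = loci_log_likelihood(trees, p0)
        b = loci_log_likelihood(trees, p_eps)
        assert np.isfinite(a)
        assert b == pytest.approx(a, rel=1e-8)

    def test_tau_zero_recovers_kingman(self, mig_trees):
        """At tau = 0 the density is the single-population coalescent with theta3."""
        theta3 = 7.0
        p = IMParams(3.0, 4.0, theta3, 0.15, 0.05, 0.0)
        for tree in mig_trees[:20]:
            expected = 0.0
            prev = 0.0
            for j, t in enumerate(tree.times):
                k = tree.n_tips - j
                expected += -k * (k - 1) * (t - prev) / theta3 + math.log(2 / theta3)
                prev = t
            assert gene_tree_log_density(tree, p) == pytest.approx(expected, abs=1e-8)

    def test_invariant_under_within_population_relabeling(self, mig_trees):
        p = IMParams(9.0, 11.0, 10.0, 0.12, 0.04, 8.0)
        swap = {"P1_1": "P1_2", "P1_2": "P1_1", "P2_1": "P2_2", "P2_2": "P2_1"}
        for tree in mig_trees[:20]:
            assert gene_tree_log_density(tree.relabel(swap), p) == pytest.approx(
                gene_tree_log_density(tree, p), rel=1e-10
            )

    @pytest.mark.parametrize(
        "params",
        [
            IMParams(10, 10, 10, 0.1, 0.0, 10),
            IMParams(5, 20, 8, 0.2, 0.2, 2.5),
            IMParams(10, 10, 10, 0.0, 0.0, 0.5),
            IMParams(30, 2, 15, 0.01, 0.15, 19.0),
        ],
    )
    def test_vectorized_engine_matches_reference(self, mig_trees, params):
        """The batch engine and the per-tree expm route are independent paths."""
        engine = LociLikelihood(mig_trees)
        batch = engine.per_tree_log_density(params)
        reference = np.array([gene_tree_log_density(t, params) for t in mig_trees])
        assert batch == pytest.approx(reference, rel=1e-8)

    def test_loci_likelihood_additivity(self, mig_trees):
        p = IMParams(10, 10, 10, 0.1, 0.0, 10)
        one = loci_log_likelihood(mig_trees[:1], p)
        assert one == pytest.approx(gene_tree_log_density(mig_trees[0], p))
        doubled = loci_log_likelihood(mig_trees[:1] * 2, p)
        assert doubled == pytest.approx(2 * one, rel=1e-12)

    def test_any_impossible_tree_poisons_the_sum(self):
        p = IMParams(10, 10, 10, 0, 0, 10)
        good = two_tip_tree(12.0, pops=(1, 2))
        bad = two_tip_tree(5.0, pops=(1, 2))
        assert loci_log_likelihood([good, bad], p) == -math.inf

    def test_empty_tree_list_rejected(self):
        with pytest.raises(ValueError):
            loci_log_likelihood([], IMParams(10, 10, 10))


class TestSchedule:
    def test_split_marker_position(self):
        tree = four_tip_tree(1.0, 2.0, 3.0)
        assert build_schedule(tree, 2.5).n_pre_split == 2
        assert build_schedule(tree, 0.0).n_pre_split == 0
        assert build_schedule(tree, 20.0).n_pre_split == 3

    def test_event_at_exactly_tau_is_ancestral(self):
        tree = four_tip_tree(1.0, 2.0, 3.0)
        assert build_schedule(tree, 2.0).n_pre_split == 1

    def test_merge_pairs_tracked_in_slot_space(self):
        schedule = build_schedule(four_tip_tree(1.0, 2.0, 3.0), 2.5)
        # pop-1 cherry merges slots (0, 1); pop-2 cherry then occupies (1, 2)
        assert schedule.merges[0] == (0, 1)
        assert schedule.merges[1] == (1, 2)
        assert schedule.merges[2] == (0, 1)
        assert schedule.slot_pops == (1, 1, 2, 2)
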