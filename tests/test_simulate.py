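import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from imcoal import (
    ARGLocus,
    IMParams,
    SimulationConfig,
    marginal_tree,
    simulate_loci,
    simulate_locus,
)

from conftest import four_tip_tree


def _mc_mean_check(sample, expected, label=""):
    se = sample.std(ddof=1) / np.sqrt(sample.size)
    assert abs(sample.mean() - expected) < 3 * se, (
        f"{label}: mean {sample.mean():.4f} vs expected {expected} (SE {se:.4f})"
    )


class TestStructure:
    def test_no_recombination_gives_single_block(self):
        cfg = SimulationConfig(params=IMParams(10, 10, 10, 0, 0, 2.5), rho=0.0, seed=1)
        for locus in simulate_loci(cfg, 20):
            assert locus.breakpoints == ()
            assert locus.n_blocks == 1
            assert locus.blocks[0][:2] == (0.0, 1.0)

    def test_blocks_tile_unit_interval(self):
        cfg = SimulationConfig(params=IMParams(10, 10, 10, 0.1, 0, 10), rho=1.0, seed=2)
        for locus in simulate_loci(cfg, 20):
            assert locus.n_blocks == len(locus.breakpoints) + 1
            edges = [0.0] + list(locus.breakpoints) + [1.0]
            for (start, end, _), lo, hi in zip(locus.blocks, edges[:-1], edges[1:]):
                assert (start, end) == (lo, hi)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(
        seed=st.integers(0, 10**6),
        rho=st.sampled_from([0.0, 0.2, 1.0]),
        tau=st.sampled_from([0.0, 0.5, 10.0]),
        m1=st.sampled_from([0.0, 0.1]),
    )
    def test_every_block_tree_is_valid(self, seed, rho, tau, m1):
        """Block trees are ultrametric with the configured tip set (any scenario)."""
        cfg = SimulationConfig(
            params=IMParams(10, 10, 10, m1, 0, tau), rho=rho, seed=seed
        )
        locus = simulate_locus(cfg)
        for _, _, tree in locus.blocks:
            # GeneTree construction enforces ultrametric ordering; check tips
            assert tree.tip_labels == ("P1_1", "P1_2", "P2_1", "P2_2")
            assert tree.tip_pops == (1, 1, 2, 2)
            assert list(tree.times) == sorted(tree.times)

    def test_deterministic_given_seed(self):
        cfg = SimulationConfig(params=IMParams(10, 10, 10, 0.1, 0, 10), rho=1.0, seed=9)
        a = simulate_locus(cfg)
        b = simulate_locus(cfg)
        assert a.breakpoints == b.breakpoints
        assert all(x[2].times == y[2].times for x, y in zip(a.blocks, b.blocks))

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(params=IMParams(10, 10, 10), rho=-1.0)
        with pytest.raises(ValueError):
            SimulationConfig(params=IMParams(10, 10, 10), samples_per_pop=0)
        with pytest.raises(ValueError):
            IMParams(10, 10, float("nan"))


class TestMarginalTree:
    def _locus(self):
        trees = [four_tip_tree(1.0, 2.0, 3.0 + i) for i in range(4)]
        bps = (0.25, 0.5, 0.75)
        edges = (0.0,) + bps + (1.0,)
        blocks = tuple(
            (lo, hi, t) for lo, hi, t in zip(edges[:-1], edges[1:], trees)
        )
        return ARGLocus(breakpoints=bps, blocks=blocks), trees

    def test_lookup_and_boundary_ownership(self):
        locus, trees = self._locus()
        assert marginal_tree(locus, 0.0) is trees[0]
        # a breakpoint position belongs to the block starting there (half-open)
        assert marginal_tree(locus, 0.25) is trees[1]
        assert marginal_tree(locus, 0.999) is trees[3]

    def test_position_outside_unit_interval(self):
        locus, _ = self._locus()
        with pytest.raises(ValueError):
            marginal_tree(locus, 1.0)
        with pytest.raises(ValueError):
            marginal_tree(locus, -0.1)


class TestCoalescentDistributions:
    def test_kingman_tmrca_mean_and_variance(self):
        """tau = 0 reduces to the single-population coalescent: analytic TMRCA moments."""
        theta = 10.0
        cfg = SimulationConfig(params=IMParams(10, 10, theta, 0, 0, 0), rho=0.0)
        loci = simulate_loci(cfg, 10_000, seed=101)
        tmrca = np.array([l.blocks[0][2].tmrca for l in loci])
        expected_mean = sum(theta / (k * (k - 1)) for k in (4, 3, 2))
        expected_var = sum((theta / (k * (k - 1))) ** 2 for k in (4, 3, 2))
        _mc_mean_check(tmrca, expected_mean, "TMRCA mean")
        var = tmrca.var(ddof=1)
        m4 = ((tmrca - tmrca.mean()) ** 4).mean()
        se_var = np.sqrt((m4 - var**2) / tmrca.size)
        assert abs(var - expected_var) < 3 * se_var

    def test_within_population_pair_coalescence_mean(self):
        """Before a distant split the pop-1 pair coalesces at rate 2/theta1."""
        cfg = SimulationConfig(params=IMParams(10, 10, 10, 0, 0, 20), rho=0.0)
        loci = simulate_loci(cfg, 10_000, seed=103)
        pair = np.array([l.blocks[0][2].mrca_time(0, 1) for l in loci])
        _mc_mean_check(pair, 5.0, "pop-1 pair mean")

    def test_no_cross_population_coalescence_without_migration(self):
        cfg = SimulationConfig(params=IMParams(10, 10, 10, 0, 0, 20), rho=0.0)
        loci = simulate_loci(cfg, 500, seed=105)
        for locus in loci:
            assert locus.blocks[0][2].mrca_time(0, 2) >= 20.0


class TestAgainstMsprime:
    """Distributional agreement with an independent coalescent simulator."""

    @staticmethod
    def _msprime_demography(p, msprime):
        d = msprime.Demography()
        d.add_population(name="A", initial_size=p.theta1 / 4)
        d.add_population(name="B", initial_size=p.theta2 / 4)
        d.add_population(name="C", initial_size=p.theta3 / 4)
        d.set_migration_rate(source="A", dest="B", rate=p.m1)
        d.set_migration_rate(source="B", dest="A", rate=p.m2)
        d.add_population_split(time=p.tau, derived=["A", "B"], ancestral="C")
        return d

    @staticmethod
    def _visible_breakpoints(locus):
        count = 0
        for (_, _, left), (_, _, right) in zip(locus.blocks[:-1], locus.blocks[1:]):
            if not np.allclose(sorted(left.times), sorted(right.times)):
                count += 1
        return count

    def test_matched_scaled_parameters(self):
        msprime = pytest.importorskip("msprime")
        p = IMParams(10, 10, 10, 0.1, 0.0, 10)
        rho, n = 1.0, 10_000
        loci = simulate_loci(SimulationConfig(params=p, rho=rho), n, seed=107)
        ours = {
            "breakpoints": np.array([self._visible_breakpoints(l) for l in loci], float),
            "pair_within": np.array(
                [marginal_tree(l, 0.5).mrca_time(0, 1) for l in loci]
            ),
            "pair_cross": np.array(
                [marginal_tree(l, 0.5).mrca_time(0, 2) for l in loci]
            ),
        }
        theirs = {k: [] for k in ours}
        reps = msprime.sim_ancestry(
            samples={"A": 1, "B": 1},
            demography=self._msprime_demography(p, msprime),
            sequence_length=1,
            recombination_rate=rho,
            discrete_genome=False,
            ploidy=2,
            num_replicates=n,
            random_seed=709,
        )
        for ts in reps:
            theirs["breakpoints"].append(ts.num_trees - 1)
            tr = ts.at(0.5)
            s = list(ts.samples())
            theirs["pair_within"].append(tr.tmrca(s[0], s[1]))
            theirs["pair_cross"].append(tr.tmrca(s[0], s[2]))
        for key in ours:
            a, b = ours[key], np.asarray(theirs[key], dtype=float)
            se = np.hypot(a.std(ddof=1) / np.sqrt(n), b.std(ddof=1) / np.sqrt(n))
            assert abs(a.mean() - b.mean()) < 3 * se, (
                f"{key}: {a.mean():.3f} vs {b.mean():.3f} (SE {se:.3f})"
            )
            # variances via the large-sample SE of a sample variance
            va, vb = a.var(ddof=1), b.var(ddof=1)
            se_v = np.hypot(
                np.sqrt((((a - a.mean()) ** 4).mean() - va**2) / n),
                np.sqrt((((b - b.mean()) ** 4).mean() - vb**2) / n),
            )
            assert abs(va - vb) < 3 * se_v, f"{key} variance: {va:.3f} vs {vb:.3f}"
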