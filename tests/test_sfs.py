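import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sfscl import (
    AscertainmentScheme,
    Demography,
    ObservedSFS,
    collapse_entries,
    estimate_expected_pairwise,
    estimate_expected_sfs,
    estimate_p0,
    marginal_pair,
    simulate_observed_sfs,
)
from sfscl.benchmarks import scenario_preset


class TestObservedSFS:
    def test_polymorphic_count_excludes_absorbing_corners(self):
        counts = np.array([100, 3, 2, 1, 50])
        obs = ObservedSFS(sample_sizes=(4,), counts=counts)
        assert obs.S == 6

    def test_l_smaller_than_s_rejected(self):
        with pytest.raises(ValueError, match="smaller than"):
            ObservedSFS(sample_sizes=(2,), counts=[0, 5, 0], L=3)

    def test_marginal_pair_projects_joint_counts(self):
        rng = np.random.default_rng(0)
        counts = rng.integers(0, 5, size=(3, 4, 5))
        obs = ObservedSFS(sample_sizes=(2, 3, 4), counts=counts)
        m = marginal_pair(obs, 0, 2)
        assert m.sample_sizes == (2, 4)
        assert np.array_equal(m.counts, counts.sum(axis=1))


class TestExpectedSFS:
    def test_two_lineages_have_one_class(self):
        d = Demography(sizes=[777], sample_sizes=[2])
        e = estimate_expected_sfs(d, 50, np.random.default_rng(0))
        assert e.probs.ravel()[1] == pytest.approx(1.0)

    def test_neutral_closed_form(self, one_deme, rng):
        e = estimate_expected_sfs(one_deme, 30_000, rng)
        i = np.arange(1, 20)
        expect = (1 / i) / np.sum(1 / i)
        assert np.abs(e.probs.ravel()[1:20] - expect).max() < 0.01

    def test_probabilities_sum_to_one(self, pair_deme, rng):
        e = estimate_expected_sfs(pair_deme, 5_000, rng)
        assert e.probs.sum() == pytest.approx(1.0)
        assert np.all(e.probs >= 0)

    def test_z_zero_rejected(self, one_deme, rng):
        with pytest.raises(ValueError, match="Z"):
            estimate_expected_sfs(one_deme, 0, rng)

    def test_matches_tree_based_accumulation(self, pair_deme):
        # kernel vs the explicit-tree reference implementation
        from sfscl import simulate_genealogy

        rng = np.random.default_rng(42)
        e = estimate_expected_sfs(pair_deme, 30_000, rng)
        num = np.zeros(e.shape)
        den = 0.0
        for _ in range(3_000):
            g = simulate_genealogy(pair_deme, rng)
            bl = g.branch_lengths()
            for b, l in enumerate(bl):
                num[tuple(g.descent[b])] += l
            den += bl.sum()
        ref = num / den
        assert np.abs(ref - e.probs).max() < 0.012

    def test_pairwise_marginals_match_joint(self):
        d = Demography(
            sizes=[2_000, 2_000, 2_000],
            sample_sizes=[4, 4, 4],
            migration_matrices=[np.full((3, 3), 1e-3)],
        )
        rng = np.random.default_rng(9)
        joint = estimate_expected_sfs(d, 40_000, rng)
        pairs = estimate_expected_pairwise(d, 40_000, rng)
        # 2-D marginal of the joint == pairwise-projected estimate (both MC)
        marg01 = joint.probs.sum(axis=2)
        assert np.abs(marg01 - pairs[(0, 1)].probs).max() < 0.01


class TestAscertainment:
    def test_whole_sample_of_two_is_unchanged(self):
        d = Demography(sizes=[1_000], sample_sizes=[2])
        rng = np.random.default_rng(1)
        plain = estimate_expected_sfs(d, 2_000, rng)
        asc = estimate_expected_sfs(
            d, 2_000, rng, asc=AscertainmentScheme(deme=0)
        )
        assert asc.probs.ravel()[1] == pytest.approx(plain.probs.ravel()[1])

    def test_stationary_ascertained_shape(self, one_deme, rng):
        # p_i ∝ (n - i): singleton-depleted relative to 1/i
        e = estimate_expected_sfs(
            one_deme, 40_000, rng, asc=AscertainmentScheme(deme=0)
        )
        i = np.arange(1, 20)
        expect = (20 - i) / np.sum(20.0 - i)
        assert np.abs(e.probs.ravel()[1:20] - expect).max() < 0.01

    def test_requires_two_sampled_lineages(self):
        d = Demography(
            sizes=[1_000, 1_000],
            sample_sizes=[4, 1],
            migration_matrices=[np.full((2, 2), 1e-3)],
        )
        with pytest.raises(ValueError, match="sample size"):
            estimate_expected_sfs(
                d, 100, np.random.default_rng(0), asc=AscertainmentScheme(deme=1)
            )


class TestP0:
    def test_zero_rate_gives_one(self):
        assert estimate_p0(np.array([100.0, 5000.0]), 0.0, 50) == 1.0

    def test_pair_closed_form(self):
        # T = 2 * TMRCA ~ Exp(1/(2N)) doubled: p0 = 1/(1 + 4 N mu L)
        N, mu, L = 5_000, 1e-6, 10
        rng = np.random.default_rng(3)
        T = 2.0 * rng.exponential(2 * N, size=200_000)
        assert estimate_p0(T, mu, L) == pytest.approx(1 / (1 + 4 * N * mu * L), rel=0.01)

    def test_monotone_in_mutation_rate(self):
        T = np.array([1e4, 2e4, 3e4])
        vals = [estimate_p0(T, mu, 50) for mu in (0, 1e-8, 1e-7, 1e-6, 1e-4)]
        assert all(a >= b for a, b in zip(vals, vals[1:]))
        assert vals[-1] < 1e-6


class TestCollapse:
    def test_epsilon_zero_unchanged(self):
        out = collapse_entries(np.array([5, 0, 2]), np.array([0.5, 0.3, 0.2]), 0)
        assert np.array_equal(out.counts, [5, 0, 2])
        assert out.num_pooled == 0

    def test_worked_example(self):
        out = collapse_entries(
            np.array([10, 3, 1, 0]), np.array([0.5, 0.3, 0.15, 0.05]), 2
        )
        assert np.array_equal(out.counts, [10, 3, 1])
        assert np.allclose(out.probs, [0.5, 0.3, 0.2])
        assert out.num_pooled == 2

    def test_dims_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            collapse_entries(np.array([1, 2]), np.array([0.5, 0.3, 0.2]), 1)

    @settings(max_examples=50, deadline=None)
    @given(
        counts=st.lists(st.integers(0, 20), min_size=2, max_size=30),
        epsilon=st.integers(0, 10),
        seed=st.integers(0, 10_000),
    )
    def test_totals_conserved_and_classes_shrink(self, counts, epsilon, seed):
        counts = np.array(counts)
        probs = np.random.default_rng(seed).dirichlet(np.ones(len(counts)))
        out = collapse_entries(counts, probs, epsilon)
        assert out.counts.sum() == counts.sum()
        assert out.probs.sum() == pytest.approx(probs.sum())
        assert out.num_classes <= len(counts)


class TestPseudoData:
    def test_zero_mutation_rate_gives_empty_spectrum(self, one_deme, rng):
        obs = simulate_observed_sfs(one_deme, 100, 50, 0.0, rng)
        assert obs.S == 0
        assert obs.L == 5_000

    def test_watterson_expected_s(self, one_deme, rng):
        # E[S] = 4 N mu L_total H_{n-1}
        obs = simulate_observed_sfs(one_deme, 20_000, 50, 2.5e-8, rng)
        expect = 4 * 10_000 * 2.5e-8 * 20_000 * 50 * np.sum(1 / np.arange(1, 20))
        assert obs.S == pytest.approx(expect, rel=0.1)

    def test_sfs_mean_converges_to_expected(self, rng):
        # pseudo-data frequencies approach the branch-ratio estimate
        preset = scenario_preset("bottleneck")
        d = preset.demography()
        e = estimate_expected_sfs(d, 50_000, rng)
        obs = simulate_observed_sfs(d, 30_000, 50, 2.5e-7, rng)
        freqs = obs.counts.ravel() / obs.S
        assert np.abs(freqs - e.probs.ravel()).max() < 0.01


class TestCollapseSpectrumPair:
    def test_observed_expected_pair_dispatch(self):
        from sfscl import ExpectedSFS

        obs = ObservedSFS(sample_sizes=(4,), counts=[0, 10, 3, 1, 0])
        exp = ExpectedSFS(
            sample_sizes=(4,), probs=[0.0, 0.5, 0.3, 0.2, 0.0], Z=1
        )
        out = collapse_entries(obs, exp, 2)
        assert np.array_equal(out.counts, [10, 3, 1])
        assert np.allclose(out.probs, [0.5, 0.3, 0.2])
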