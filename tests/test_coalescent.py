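import numpy as np
import pytest
from scipy import stats

from sfscl import (
    Demography,
    Genealogy,
    HistoricalEvent,
    ascertain_subtree,
    drop_mutations,
    simulate_genealogy,
    total_tree_length,
)


def hand_tree():
    """Balanced 4-leaf tree: cherries at t=1 and t=2, root at t=3."""
    parent = np.array([4, 4, 5, 5, 6, 6, -1])
    time = np.array([0.0, 0, 0, 0, 1, 2, 3])
    return Genealogy(
        num_demes=1,
        leaf_deme=np.zeros(4, dtype=np.int64),
        parent=parent,
        time=time,
    )


class TestSimulate:
    def test_pair_tmrca_mean_is_2n(self):
        # E[TMRCA] = 2N for a sample of two
        N = 5_000
        d = Demography(sizes=[N], sample_sizes=[2])
        rng = np.random.default_rng(11)
        tm = np.array([simulate_genealogy(d, rng).tmrca for _ in range(20_000)])
        assert tm.mean() == pytest.approx(2 * N, rel=0.03)

    def test_triple_total_length_mean_is_6n(self):
        # E[T] = 4N (1 + 1/2) = 6N for n = 3
        N = 5_000
        d = Demography(sizes=[N], sample_sizes=[3])
        rng = np.random.default_rng(12)
        tot = np.array(
            [simulate_genealogy(d, rng).total_length for _ in range(20_000)]
        )
        assert tot.mean() == pytest.approx(6 * N, rel=0.03)

    def test_non_closable_model_raises(self):
        d = Demography(sizes=[1_000, 1_000], sample_sizes=[3, 3])
        with pytest.raises(ValueError, match="non-closable"):
            simulate_genealogy(d, np.random.default_rng(0))

    def test_same_seed_bit_identical(self, pair_deme):
        g1 = simulate_genealogy(pair_deme, np.random.default_rng(5))
        g2 = simulate_genealogy(pair_deme, np.random.default_rng(5))
        assert np.array_equal(g1.time, g2.time)
        assert np.array_equal(g1.parent, g2.parent)

    def test_waiting_times_exponential_per_level(self):
        # first coalescence among j lineages ~ Exp(C(j,2)/(2N))
        N, n = 2_000, 6
        d = Demography(sizes=[N], sample_sizes=[n])
        rng = np.random.default_rng(13)
        waits = np.array(
            [np.diff(np.sort(simulate_genealogy(d, rng).time[n:]), prepend=0.0)
             for _ in range(4_000)]
        )
        for level, j in enumerate(range(n, n - 2, -1)):
            rate = j * (j - 1) / (4 * N)
            ks = stats.kstest(waits[:, level], "expon", args=(0, 1 / rate))
            assert ks.pvalue > 1e-3

    def test_descent_vectors_are_consistent(self, pair_deme):
        rng = np.random.default_rng(14)
        g = simulate_genealogy(pair_deme, rng)
        n = g.num_leaves
        totals = g.descent.sum(axis=1)
        # no branch subtends the whole sample or nothing
        assert np.all(totals[: 2 * n - 2] >= 1)
        assert np.all(totals[: 2 * n - 2] <= n - 1)
        # every internal node's vector equals the sum of its children's
        for p in range(n, 2 * n - 1):
            kids = np.nonzero(g.parent == p)[0]
            assert np.array_equal(g.descent[kids].sum(axis=0), g.descent[p])
        assert np.array_equal(g.descent[g.root], [6, 4])

    def test_growth_shrinks_tmrca(self):
        # forward growth => smaller past sizes => faster coalescence
        N = 10_000
        base = Demography(sizes=[N], sample_sizes=[2])
        grown = Demography(sizes=[N], sample_sizes=[2], growth_rates=[1e-3])
        rng = np.random.default_rng(15)
        t_base = np.mean([simulate_genealogy(base, rng).tmrca for _ in range(3_000)])
        t_grown = np.mean([simulate_genealogy(grown, rng).tmrca for _ in range(3_000)])
        assert t_grown < 0.5 * t_base


class TestTreeLength:
    def test_two_leaf_tree_is_twice_tmrca(self):
        d = Demography(sizes=[1_000], sample_sizes=[2])
        g = simulate_genealogy(d, np.random.default_rng(2))
        assert total_tree_length(g) == pytest.approx(2 * g.tmrca)

    def test_hand_tree_sum(self):
        # branches: 1+1 (first cherry), 2+2, 2 (node4->root at 3), 1 (node5->root)
        assert total_tree_length(hand_tree()) == pytest.approx(9.0)

    def test_equals_child_parent_gaps(self, pair_deme):
        g = simulate_genealogy(pair_deme, np.random.default_rng(3))
        gaps = g.time[g.parent[: 2 * g.num_leaves - 2]] - g.time[: 2 * g.num_leaves - 2]
        assert total_tree_length(g) == pytest.approx(gaps.sum())


class TestMutations:
    def test_zero_rate_gives_no_mutations(self):
        g = hand_tree()
        out = drop_mutations(g, 0.0, 50, np.random.default_rng(0))
        assert out.shape == (0, 1)

    def test_poisson_mean_matches_mu_l_t(self):
        g = hand_tree()  # T = 9
        mu, L = 1e-3, 100
        rng = np.random.default_rng(4)
        counts = [len(drop_mutations(g, mu, L, rng)) for _ in range(4_000)]
        assert np.mean(counts) == pytest.approx(mu * L * 9, rel=0.05)

    def test_neutral_sfs_from_mutations(self, one_deme):
        # frequency classes ~ (1/i)/H_{n-1} for a constant-size deme
        rng = np.random.default_rng(6)
        n = 20
        counts = np.zeros(n + 1)
        for _ in range(3_000):
            g = simulate_genealogy(one_deme, rng)
            muts = drop_mutations(g, 5e-7, 50, rng)
            np.add.at(counts, muts[:, 0], 1)
        i = np.arange(1, n)
        expect = (1 / i) / np.sum(1 / i)
        freqs = counts[1:n] / counts[1:n].sum()
        assert np.abs(freqs - expect).max() < 0.02


class TestAscertainSubtree:
    def test_two_leaf_sample_subtree_is_whole_tree(self):
        d = Demography(sizes=[1_000], sample_sizes=[2])
        g = simulate_genealogy(d, np.random.default_rng(8))
        sub = ascertain_subtree(g, 0, np.random.default_rng(9))
        assert sub.total_length == pytest.approx(g.total_length)

    def test_subtree_on_hand_tree(self):
        g = hand_tree()
        rng = np.random.default_rng(0)
        for _ in range(20):
            sub = ascertain_subtree(g, 0, rng)
            a, b = sub.pair
            # cherry mates meet at their cherry; cross-cherry pairs at the root
            if {a, b} == {0, 1}:
                assert sub.total_length == pytest.approx(2.0)
            elif {a, b} == {2, 3}:
                assert sub.total_length == pytest.approx(4.0)
            else:
                # leaf->cherry->root on both sides: (1+2) + (2+1)
                assert sub.total_length == pytest.approx(6.0)

    def test_needs_two_lineages(self, pair_deme):
        d = Demography(
            sizes=[1_000, 1_000],
            sample_sizes=[3, 1],
            events=[HistoricalEvent(time=100, source=1, sink=0)],
        )
        g = simulate_genealogy(d, np.random.default_rng(1))
        with pytest.raises(ValueError, match="need >= 2"):
            ascertain_subtree(g, 1, np.random.default_rng(1))

    def test_exchangeability_of_deme_relabelling(self, one_deme):
        # subtree lengths are exchangeable across which leaves were drawn
        rng = np.random.default_rng(10)
        g = simulate_genealogy(one_deme, rng)
        lens = [ascertain_subtree(g, 0, rng).total_length for _ in range(50)]
        assert min(lens) > 0
        assert max(lens) <= g.total_length + 1e-9


class TestNewick:
    def test_hand_tree_newick(self):
        s = hand_tree().newick()
        assert s.endswith(";")
        assert s.count("(") == 3
        assert "l0" in s and "l3" in s
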