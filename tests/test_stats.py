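"""Statistical-primitive tests against enumeration oracles."""

import itertools
from math import comb

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vaxendo.stats import (
    adjusted_rand_index,
    auroc,
    bh_adjust,
    fisher_exact_2x2,
    kruskal_wallis,
    spearman,
    wilcoxon_rank_sum,
)


def hypergeom_two_sided_p(table):
    """Brute-force two-sided Fisher p: sum of hypergeometric probabilities of
    tables (same margins) no more probable than the observed one."""
    a, b = table[0]
    c, d = table[1]
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2

    def prob(x):
        return comb(r1, x) * comb(r2, c1 - x) / comb(n, c1)

    observed = prob(a)
    lo, hi = max(0, c1 - r2), min(r1, c1)
    return sum(prob(x) for x in range(lo, hi + 1) if prob(x) <= observed * (1 + 1e-9))


def ranksum_exhaustive_p(x, y):
    """Two-sided exhaustive permutation p for the rank-sum statistic."""
    from scipy.stats import rankdata

    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    n1 = len(x)
    observed = ranks[:n1].sum()
    sums = [
        sum(ranks[list(idx)])
        for idx in itertools.combinations(range(len(pooled)), n1)
    ]
    sums = np.array(sums)
    eps = 1e-9
    return min(1.0, 2 * min((sums <= observed + eps).mean(), (sums >= observed - eps).mean()))


class TestFisherExact:
    def test_diagonal_5_0_0_5(self):
        res = fisher_exact_2x2([[5, 0], [0, 5]])
        assert res.p_value == pytest.approx(2 / 252, rel=1e-9)
        assert res.exact_flag

    def test_zero_margin_p_one(self):
        assert fisher_exact_2x2([[0, 0], [3, 4]]).p_value == 1.0

    def test_independence_balanced_table(self):
        res = fisher_exact_2x2([[2, 2], [2, 2]])
        assert res.statistic == pytest.approx(1.0)
        assert res.p_value == pytest.approx(1.0)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact_2x2([[1, -1], [0, 2]])

    @given(
        st.tuples(
            st.integers(0, 8), st.integers(0, 8), st.integers(0, 8), st.integers(0, 8)
        )
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_matches_hypergeometric_enumeration(self, cells):
        a, b, c, d = cells
        table = [[a, b], [c, d]]
        res = fisher_exact_2x2(table)
        assert res.p_value == pytest.approx(hypergeom_two_sided_p(table), rel=1e-6, abs=1e-12)


class TestWilcoxonRankSum:
    @given(
        st.lists(st.integers(-5, 5), min_size=2, max_size=4),
        st.lists(st.integers(-5, 5), min_size=2, max_size=4),
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_matches_exhaustive_enumeration_small_n(self, x, y):
        x, y = np.array(x, float), np.array(y, float)
        res = wilcoxon_rank_sum(x, y)
        assert res.exact_flag
        assert res.p_value == pytest.approx(ranksum_exhaustive_p(x, y), abs=1e-12)

    def test_tie_free_exact_example(self):
        res = wilcoxon_rank_sum([1.0, 2.0, 3.0], [4.0, 5.0, 6.0])
        assert res.p_value == pytest.approx(0.1)

    def test_large_samples_use_normal_approximation(self, rng):
        res = wilcoxon_rank_sum(rng.normal(0, 1, 30), rng.normal(0.5, 1, 30))
        assert not res.exact_flag
        assert res.method == "wilcoxon-normal"

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum([], [1.0])


def kruskal_exhaustive_p(groups):
    """Independent oracle: exact KW permutation p via full n! enumeration."""
    from scipy.stats import rankdata

    pooled = np.concatenate(groups)
    ranks = rankdata(pooled)
    n = len(pooled)
    _, counts = np.unique(pooled, return_counts=True)
    tie = 1.0 - (counts**3 - counts).sum() / (n**3 - n)
    sizes = [len(g) for g in groups]

    def h_of(order):
        h, start = 0.0, 0
        r = ranks[list(order)]
        for m in sizes:
            h += r[start : start + m].sum() ** 2 / m
            start += m
        return (12.0 / (n * (n + 1)) * h - 3 * (n + 1)) / tie

    observed = h_of(range(n))
    perms = [h_of(p) for p in itertools.permutations(range(n))]
    return observed, np.mean(np.array(perms) >= observed - 1e-9)


class TestKruskalWallis:
    @given(
        st.lists(st.integers(0, 3), min_size=2, max_size=3),
        st.lists(st.integers(0, 3), min_size=2, max_size=3),
        st.lists(st.integers(0, 3), min_size=2, max_size=2),
    )
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_matches_exhaustive_enumeration_small_n(self, a, b, c):
        from hypothesis import assume

        assume(len(set(a + b + c)) > 1)  # all-constant input has no test to run
        groups = [np.array(a, float), np.array(b, float), np.array(c, float)]
        res = kruskal_wallis(*groups)
        stat, p = kruskal_exhaustive_p(groups)
        assert res.exact_flag
        assert res.statistic == pytest.approx(stat, abs=1e-9)
        assert res.p_value == pytest.approx(p, abs=1e-12)

    def test_two_groups_matches_wilcoxon_without_continuity(self, rng):
        x = rng.normal(0, 1, 40)
        y = rng.normal(0.4, 1, 35)
        kw = kruskal_wallis(x, y)
        wrs = wilcoxon_rank_sum(x, y, use_continuity=False, force_asymptotic=True)
        assert kw.p_value == pytest.approx(wrs.p_value, abs=1e-6)

    def test_identical_constant_groups(self):
        res = kruskal_wallis([1.0, 1.0], [1.0, 1.0])
        assert res.p_value == 1.0

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            kruskal_wallis([1.0, 2.0])


class TestSpearman:
    def test_monotone_transform_gives_rho_one(self, rng):
        x = rng.normal(0, 1, 25)
        assert spearman(x, np.exp(x)).statistic == pytest.approx(1.0)

    def test_reversed_gives_minus_one(self):
        x = np.arange(10.0)
        assert spearman(x, -(x**3)).statistic == pytest.approx(-1.0)


class TestBhAdjust:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.03])[0] == pytest.approx(0.03)

    def test_two_value_closed_form(self):
        assert np.allclose(bh_adjust([0.01, 0.04]), [0.02, 0.04])

    def test_four_value_closed_form(self):
        assert np.allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04])

    def test_all_equal_unchanged(self):
        assert np.allclose(bh_adjust([0.2, 0.2, 0.2]), [0.2, 0.2, 0.2])

    @given(st.lists(st.floats(1e-6, 1.0), min_size=1, max_size=20))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_monotone_in_raw_p_and_capped(self, ps):
        adj = bh_adjust(ps)
        assert (adj <= 1.0 + 1e-12).all()
        assert (adj >= np.asarray(ps) - 1e-12).all()
        order = np.argsort(ps)
        assert (np.diff(adj[order]) >= -1e-12).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.0, 0.5])


class TestAuroc:
    def test_perfect_separation(self):
        assert auroc([1, 2, 3, 10, 11], [0, 0, 0, 1, 1]) == 1.0

    def test_all_scores_equal_gives_half(self):
        assert auroc([5, 5, 5, 5], [0, 1, 0, 1]) == 0.5

    @given(
        st.lists(st.integers(-4, 4), min_size=4, max_size=12),
        st.integers(0, 2**30),
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_matches_pairwise_oracle(self, scores, seed):
        rng = np.random.default_rng(seed)
        labels = rng.integers(0, 2, len(scores))
        if labels.sum() in (0, len(labels)):
            labels[0] = 1 - labels[0]
        scores = np.array(scores, float)
        pos = scores[labels == 1]
        neg = scores[labels == 0]
        oracle = np.mean(
            [(1.0 if p > n else 0.5 if p == n else 0.0) for p in pos for n in neg]
        )
        assert auroc(scores, labels) == pytest.approx(oracle, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auroc([1, 2], [1, 1])


class TestAdjustedRandIndex:
    def test_identical_partitions(self):
        assert adjusted_rand_index([0, 0, 1, 1], [5, 5, 9, 9]) == 1.0

    def test_independent_partitions_near_zero(self, rng):
        a = rng.integers(0, 3, 300)
        b = rng.integers(0, 3, 300)
        assert abs(adjusted_rand_index(a, b)) < 0.1
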