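"""Shared statistical primitives used across the pipeline.

Thin, convention-pinning wrappers around scipy/sklearn: two-sided Fisher's
exact test (probability-mass method), Wilcoxon rank-sum with an exact path
for small samples, Kruskal-Wallis, Spearman correlation, Benjamini-Hochberg
adjustment, rank-based auROC and the adjusted Rand index. Each returns plain
floats / small result objects so downstream tables stay serializable.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from sklearn.metrics import adjusted_rand_score

#: Combined sample size at or below which the rank-sum test is exact.
EXACT_WILCOXON_N = 25
#: Combined size at or below which ties are handled by full enumeration.
EXACT_TIES_N = 12


@dataclass
class TestResult:
    """Outcome of a hypothesis test.

    ``exact_flag`` is True when the p-value was computed by enumeration of
    the permutation/hypergeometric null rather than an approximation.
    """

    statistic: float
    p_value: float
    method: str
    exact_flag: bool


def _exact_ranksum_enumeration(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided exact rank-sum p by enumerating all group assignments.

    Handles ties via midranks. p = 2 * min(P(W <= w), P(W >= w)) capped at 1,
    matching the standard exact two-sided convention.
    """
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    n1 = len(x)
    observed = ranks[:n1].sum()
    sums = np.array(
        [sum(ranks[list(idx)]) for idx in itertools.combinations(range(len(pooled)), n1)]
    )
    eps = 1e-9
    p_low = np.mean(sums <= observed + eps)
    p_high = np.mean(sums >= observed - eps)
    return float(min(1.0, 2.0 * min(p_low, p_high)))


def wilcoxon_rank_sum(
    x, y, use_continuity: bool = True, force_asymptotic: bool = False
) -> TestResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Exact for combined n <= 25 (full enumeration when ties are present and
    combined n <= 12); otherwise the normal approximation, with continuity
    correction by default. The statistic reported is the Mann-Whitney U of
    the first sample.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be non-empty")
    n = len(x) + len(y)
    has_ties = len(np.unique(np.concatenate([x, y]))) < n
    u_stat = float(sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic").statistic)
    if not force_asymptotic and n <= EXACT_WILCOXON_N and not has_ties:
        res = sps.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        return TestResult(float(res.statistic), float(res.pvalue), "wilcoxon-exact", True)
    if not force_asymptotic and n <= EXACT_TIES_N:
        p = _exact_ranksum_enumeration(x, y)
        return TestResult(u_stat, p, "wilcoxon-exact-ties", True)
    res = sps.mannwhitneyu(
        x, y, alternative="two-sided", method="asymptotic", use_continuity=use_continuity
    )
    return TestResult(float(res.statistic), float(res.pvalue), "wilcoxon-normal", False)


def fisher_exact_2x2(table) -> TestResult:
    """Two-sided Fisher's exact test on a 2x2 count table.

    Two-sided p is the sum of hypergeometric probabilities of all tables at
    least as unlikely as the observed one (probability-mass method).
    """
    table = np.asarray(table)
    if table.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if (table < 0).any() or not np.issubdtype(table.dtype, np.integer):
        if (table < 0).any() or not np.allclose(table, np.round(table)):
            raise ValueError("counts must be non-negative integers")
        table = table.astype(int)
    odds, p = sps.fisher_exact(table, alternative="two-sided")
    return TestResult(float(odds), float(p), "fisher-exact", True)


#: Combined size at or below which Kruskal-Wallis uses the exact permutation null.
EXACT_KRUSKAL_N = 10


def _kruskal_h(pooled_ranks: np.ndarray, sizes: list[int], tie_term: float) -> float:
    n = len(pooled_ranks)
    h = 0.0
    start = 0
    for m in sizes:
        h += pooled_ranks[start : start + m].sum() ** 2 / m
        start += m
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    return h / tie_term if tie_term > 0 else 0.0


def _exact_kruskal_p(arrays: list[np.ndarray]) -> tuple[float, float]:
    """Exact permutation p for the (tie-corrected) H statistic."""
    pooled = np.concatenate(arrays)
    ranks = sps.rankdata(pooled)
    n = len(pooled)
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = 1.0 - (counts**3 - counts).sum() / (n**3 - n)
    sizes = [len(a) for a in arrays]
    observed = _kruskal_h(ranks, sizes, tie_term)

    stats: list[float] = []

    def _assign(remaining: tuple[int, ...], group: int, chosen: list[int]) -> None:
        if group == len(sizes) - 1:
            order = chosen + list(remaining)
            stats.append(_kruskal_h(ranks[order], sizes, tie_term))
            return
        for combo in itertools.combinations(remaining, sizes[group]):
            rest = tuple(i for i in remaining if i not in combo)
            _assign(rest, group + 1, chosen + list(combo))

    _assign(tuple(range(n)), 0, [])
    return observed, float(np.mean(np.array(stats) >= observed - 1e-9))


def kruskal_wallis(*groups, force_asymptotic: bool = False) -> TestResult:
    """Kruskal-Wallis H test.

    Exact permutation p (full enumeration of group assignments) for combined
    n <= 10; otherwise the chi-square approximation with tie correction.
    """
    if len(groups) < 2:
        raise ValueError("need >=2 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(len(a) == 0 for a in arrays):
        raise ValueError("empty group")
    pooled = np.concatenate(arrays)
    if len(np.unique(pooled)) == 1:
        return TestResult(0.0, 1.0, "kruskal-wallis", False)
    n = len(pooled)
    if not force_asymptotic and n <= EXACT_KRUSKAL_N:
        stat, p = _exact_kruskal_p(arrays)
        return TestResult(stat, p, "kruskal-wallis-exact", True)
    stat, p = sps.kruskal(*arrays)
    return TestResult(float(stat), float(p), "kruskal-wallis", False)


def spearman(x, y) -> TestResult:
    """Spearman rank correlation with its two-sided p-value."""
    rho, p = sps.spearmanr(x, y)
    return TestResult(float(rho), float(p), "spearman", False)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p <= 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    scaled = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(scaled[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adjusted, 1.0)
    return out


def auroc(scores, labels) -> float:
    """Area under the ROC curve via midranks (Mann-Whitney form, ties count 1/2)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("auROC needs both classes present")
    ranks = sps.rankdata(scores)
    return float((ranks[labels].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def adjusted_rand_index(labels_a, labels_b) -> float:
    """Adjusted Rand index between two partitions of the same items."""
    return float(adjusted_rand_score(labels_a, labels_b))
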