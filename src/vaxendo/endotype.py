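"""Pre-vaccination endotype discovery from SLEA profiles.

Samples are clustered by their gene-set activity vectors (Euclidean distance,
complete linkage); the number of clusters is selected with the Gap statistic
(uniform reference over the per-feature range, one-standard-error rule); the
three clusters are labeled low/middle/high inflammatory by the average
z-score of four hallmark inflammatory gene sets; and the trait-likeness of
the profiles is quantified by a between/total variance-ratio temporal
stability metric over repeated pre-vaccination (and late post-vaccination)
samples of the same participants.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform

from vaxendo.slea import SleaMatrix

logger = logging.getLogger(__name__)

#: The four hallmark gene sets whose mean SLEA z-score defines the
#: inflammatory score used to label endotypes.
INFLAMMATORY_SETS = (
    "HALLMARK_INFLAMMATORY_RESPONSE",
    "HALLMARK_COMPLEMENT",
    "HALLMARK_IL6_JAK_STAT3_SIGNALING",
    "HALLMARK_TNFA_SIGNALING_VIA_NFKB",
)

ENDOTYPE_LABELS = ("inflam.lo", "inflam.mid", "inflam.hi")

#: Days eligible for the temporal-stability computation: pre-vaccination
#: samples plus late samples where the vaccine response has resolved.
STABILITY_LATE_DAY = 70


def hierarchical_clusters(slea: SleaMatrix, k: int) -> pd.Series:
    """Cut a complete-linkage dendrogram of SLEA sample profiles into k clusters.

    Samples (columns) are points in gene-set space; the metric is Euclidean.
    Deterministic given the input order (scipy's linkage tie-breaking).
    """
    n = slea.zscores.shape[1]
    if k < 1 or k > n:
        raise ValueError(f"k must be in [1, {n}], got {k}")
    points = slea.zscores.to_numpy(dtype=float).T
    if k == 1:
        ids = np.ones(n, dtype=int)
    else:
        Z = linkage(points, method="complete", metric="euclidean")
        ids = fcluster(Z, t=k, criterion="maxclust")
    return pd.Series(ids, index=slea.zscores.columns, name="cluster")


def _within_dispersion(points: np.ndarray, ids: np.ndarray) -> float:
    """W_k: sum over clusters of within-cluster pairwise squared-distance
    dispersion, D_r / (2 n_r)."""
    total = 0.0
    for c in np.unique(ids):
        members = points[ids == c]
        if len(members) < 2:
            continue
        d2 = pdist(members, metric="sqeuclidean")
        total += d2.sum() / len(members)
    return total


def _cluster_ids_all_k(points: np.ndarray, k_max: int) -> np.ndarray:
    """Cluster labels for k = 1..k_max from one complete-linkage dendrogram."""
    n = len(points)
    out = np.ones((k_max, n), dtype=int)
    if n > 1:
        Z = linkage(points, method="complete", metric="euclidean")
        for k in range(2, k_max + 1):
            out[k - 1] = fcluster(Z, t=k, criterion="maxclust")
    return out


@dataclass
class GapResult:
    """Gap curve and the k chosen by the one-standard-error rule."""

    ks: np.ndarray
    gap: np.ndarray
    se: np.ndarray
    log_wk: np.ndarray
    chosen_k: int


def gap_statistic(slea: SleaMatrix, k_max: int, n_ref: int = 50, seed: int = 0) -> GapResult:
    """Select the number of clusters by the Gap statistic.

    Gap(k) = mean_ref[log W_k(ref)] - log W_k(data), with W_k the within-
    cluster pairwise dispersion and reference datasets uniform over the
    per-feature range of the data. Chosen k is the smallest k with
    Gap(k) >= Gap(k+1) - se(k+1), where se includes the simulation-error
    factor sqrt(1 + 1/B).
    """
    if k_max < 2:
        raise ValueError("k_max must be >= 2")
    if n_ref < 10:
        raise ValueError("n_ref must be >= 10")
    points = slea.zscores.to_numpy(dtype=float).T
    n = len(points)
    k_max = min(k_max, n)
    if np.allclose(points, points[0]):
        logger.warning("all samples identical; Gap statistic degenerate, k = 1")
        ks = np.arange(1, k_max + 1)
        return GapResult(ks, np.zeros(k_max), np.zeros(k_max), np.zeros(k_max), 1)

    tiny = np.finfo(float).tiny
    ids_all = _cluster_ids_all_k(points, k_max)
    log_wk = np.array(
        [np.log(max(_within_dispersion(points, ids_all[k - 1]), tiny)) for k in range(1, k_max + 1)]
    )

    rng = np.random.default_rng(seed)
    lo, hi = points.min(axis=0), points.max(axis=0)
    ref_log_wk = np.empty((n_ref, k_max))
    for b in range(n_ref):
        ref = rng.uniform(lo, hi, size=points.shape)
        ref_ids = _cluster_ids_all_k(ref, k_max)
        for k in range(1, k_max + 1):
            ref_log_wk[b, k - 1] = np.log(max(_within_dispersion(ref, ref_ids[k - 1]), tiny))

    gap = ref_log_wk.mean(axis=0) - log_wk
    se = ref_log_wk.std(axis=0, ddof=0) * np.sqrt(1.0 + 1.0 / n_ref)

    chosen = k_max
    for k in range(1, k_max):
        if gap[k - 1] >= gap[k] - se[k]:
            chosen = k
            break
    return GapResult(np.arange(1, k_max + 1), gap, se, log_wk, chosen)


@dataclass
class EndotypeAssignment:
    """Per-sample endotype assignment with diagnostics.

    ``assignments`` has one row per sample: cluster id, endotype label,
    mean inflammatory SLEA score and its tertile; ``gap`` carries the Gap
    curve when cluster-number selection was run.
    """

    assignments: pd.DataFrame
    chosen_k: int
    cluster_scores: dict[int, float]
    gap: GapResult | None = None

    def participant_consensus(self, samples: pd.DataFrame) -> pd.Series:
        """Majority endotype label across each participant's assigned samples.

        Ties are broken by the participant's mean inflammatory score
        (nearest cluster mean).
        """
        joined = self.assignments.join(samples[["participant_id"]])
        out = {}
        label_of_cluster = {c: lab for c, lab in zip(
            sorted(self.cluster_scores, key=self.cluster_scores.get), ENDOTYPE_LABELS
        )}
        score_of_label = {
            label_of_cluster[c]: s for c, s in self.cluster_scores.items()
            if c in label_of_cluster
        }
        for pid, grp in joined.groupby("participant_id"):
            counts = grp["endotype"].value_counts()
            top = counts[counts == counts.max()].index.tolist()
            if len(top) == 1:
                out[pid] = top[0]
            else:
                mean_score = grp["inflammatory_score"].mean()
                out[pid] = min(top, key=lambda lab: abs(score_of_label[lab] - mean_score))
        return pd.Series(out, name="endotype").rename_axis("participant_id")


def label_endotypes(
    clusters: pd.Series,
    slea: SleaMatrix,
    inflammatory_sets: tuple[str, ...] = INFLAMMATORY_SETS,
    gap: GapResult | None = None,
) -> EndotypeAssignment:
    """Label three clusters low/middle/high inflammatory.

    The per-sample inflammatory score is the mean SLEA z over the four
    hallmark inflammatory sets; clusters are ranked by their mean score and
    labeled inflam.lo / inflam.mid / inflam.hi. A tertile annotation of the
    score (empirical 1/3 and 2/3 quantiles over all samples, ties to the
    lower bin) is attached per sample. Labels depend only on scores, never
    on cluster numbering.
    """
    ids = clusters.unique()
    if len(ids) != 3:
        raise ValueError(
            f"endotype labeling requires exactly 3 clusters, got {len(ids)}; "
            "use generic cluster ids for other k"
        )
    missing = [s for s in inflammatory_sets if s not in slea.zscores.index]
    if missing:
        raise KeyError(f"inflammatory sets absent from SLEA matrix: {missing}")

    score = slea.zscores.loc[list(inflammatory_sets)].mean(axis=0)
    score = score.loc[clusters.index]
    cluster_scores = {int(c): float(score[clusters == c].mean()) for c in ids}
    ranked = sorted(cluster_scores, key=cluster_scores.get)
    label_of = {c: lab for c, lab in zip(ranked, ENDOTYPE_LABELS)}

    q1, q2 = np.quantile(score.to_numpy(), [1 / 3, 2 / 3])  # Hyndman-Fan type 7
    tertile = pd.Series(
        np.where(score <= q1, "low", np.where(score <= q2, "mid", "high")),
        index=score.index,
        name="tertile",
    )
    assignments = pd.DataFrame(
        {
            "cluster": clusters.astype(int),
            "endotype": clusters.map(label_of),
            "inflammatory_score": score,
            "tertile": tertile,
        }
    )
    return EndotypeAssignment(
        assignments=assignments, chosen_k=3, cluster_scores=cluster_scores, gap=gap
    )


def temporal_stability(slea: SleaMatrix, samples: pd.DataFrame) -> tuple[pd.Series, float]:
    """Between-participant variance fraction of gene-set scores over time.

    Eligible samples are pre-vaccination (day -7/0) and late post-vaccination
    (day >= 70). Per gene set, a one-way random-effects decomposition across
    participants yields stability = between-participant variance / total
    variance, truncated to [0, 1]; the aggregate is the mean over sets.
    """
    meta = samples.loc[samples.index.intersection(slea.zscores.columns)]
    eligible = meta[(meta["day"].isin([-7, 0])) | (meta["day"] >= STABILITY_LATE_DAY)]
    counts = eligible.groupby("participant_id").size()
    if len(counts) < 2:
        raise ValueError("temporal stability needs eligible samples from >=2 participants")
    if (counts < 2).all():
        raise ValueError("no participant has repeated eligible samples")

    groups = eligible.groupby("participant_id").groups
    out = {}
    for set_name in slea.zscores.index:
        values = slea.zscores.loc[set_name]
        means, ns, all_vals = [], [], []
        for pid, idx in groups.items():
            v = values.loc[idx].to_numpy(dtype=float)
            means.append(v.mean())
            ns.append(len(v))
            all_vals.append(v)
        means = np.array(means)
        ns = np.array(ns)
        grand = np.concatenate(all_vals).mean()
        N, a = ns.sum(), len(ns)
        ssb = float((ns * (means - grand) ** 2).sum())
        ssw = float(sum(((v - m) ** 2).sum() for v, m in zip(all_vals, means.tolist())))
        msw = ssw / (N - a) if N > a else 0.0
        msb = ssb / (a - 1)
        n0 = (N - (ns**2).sum() / N) / (a - 1)
        sigma_b = max(0.0, (msb - msw) / n0) if n0 > 0 else 0.0
        total = sigma_b + msw
        out[set_name] = float(np.clip(sigma_b / total, 0.0, 1.0)) if total > 0 else 0.0
    per_set = pd.Series(out, name="stability")
    return per_set, float(per_set.mean())
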