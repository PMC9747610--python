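"""Endotype tests: clustering oracle, Gap selection, labeling, stability."""

import numpy as np
import pandas as pd
import pytest

from vaxendo.endotype import (
    EndotypeAssignment,
    gap_statistic,
    hierarchical_clusters,
    label_endotypes,
    temporal_stability,
)
from vaxendo.slea import SleaMatrix
from vaxendo.stats import adjusted_rand_index


def make_slea(points, sample_ids=None, feature_names=None) -> SleaMatrix:
    """Wrap an (n_samples x n_features) array as a SleaMatrix."""
    points = np.asarray(points, dtype=float)
    n, d = points.shape
    sample_ids = sample_ids or [f"s{i}" for i in range(n)]
    feature_names = feature_names or [f"set{j}" for j in range(d)]
    z = pd.DataFrame(points.T, index=feature_names, columns=sample_ids)
    return SleaMatrix(zscores=z, effective_size={}, n_permutations=0, seed=0, dropped_sets=[])


def naive_complete_linkage_heights(points):
    """O(n^3) complete-linkage agglomeration; returns sorted merge heights."""
    clusters = [[i] for i in range(len(points))]
    heights = []
    d = np.linalg.norm(points[:, None] - points[None, :], axis=2)
    while len(clusters) > 1:
        best = (np.inf, None, None)
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                h = max(d[i, j] for i in clusters[a] for j in clusters[b])
                if h < best[0]:
                    best = (h, a, b)
        h, a, b = best
        heights.append(h)
        clusters[a] = clusters[a] + clusters[b]
        del clusters[b]
    return np.array(heights)


class TestHierarchicalClusters:
    def test_separated_blobs_recovered_perfectly(self, rng):
        centers = np.array([[0.0, 0.0], [10.0, 0.0], [0.0, 10.0]])
        labels = np.repeat([0, 1, 2], 10)
        pts = centers[labels] + rng.normal(0, 0.1, (30, 2))
        clusters = hierarchical_clusters(make_slea(pts), k=3)
        assert adjusted_rand_index(clusters.to_numpy(), labels) == 1.0

    def test_duplicate_samples_always_cocluster(self, rng):
        pts = rng.normal(0, 1, (6, 3))
        pts = np.vstack([pts, pts[2]])  # duplicate of sample 2
        for k in range(1, 7):
            clusters = hierarchical_clusters(make_slea(pts), k=k)
            assert clusters.iloc[2] == clusters.iloc[6]

    def test_merge_heights_match_naive_oracle(self, rng):
        from scipy.cluster.hierarchy import linkage

        pts = rng.normal(0, 1, (8, 4))
        ours = np.sort(linkage(pts, method="complete")[:, 2])
        oracle = np.sort(naive_complete_linkage_heights(pts))
        assert np.abs(ours - oracle).max() <= 1e-12

    def test_invalid_k_rejected(self, rng):
        slea = make_slea(rng.normal(0, 1, (5, 2)))
        with pytest.raises(ValueError):
            hierarchical_clusters(slea, k=0)
        with pytest.raises(ValueError):
            hierarchical_clusters(slea, k=6)


class TestGapStatistic:
    def test_single_blob_selects_k1(self, rng):
        pts = rng.normal(0, 1, (40, 3))
        gap = gap_statistic(make_slea(pts), k_max=5, n_ref=30, seed=1)
        assert gap.chosen_k == 1

    def test_identical_points_degenerate_k1(self):
        pts = np.ones((10, 2))
        gap = gap_statistic(make_slea(pts), k_max=4, n_ref=10, seed=1)
        assert gap.chosen_k == 1

    def test_three_blobs_select_k3(self, rng):
        centers = np.array([[0, 0], [8, 0], [0, 8]], dtype=float)
        labels = np.repeat([0, 1, 2], 15)
        pts = centers[labels] + rng.normal(0, 0.3, (45, 2))
        gap = gap_statistic(make_slea(pts), k_max=6, n_ref=50, seed=2)
        assert gap.chosen_k == 3

    def test_chosen_k_invariant_to_feature_permutation(self, rng):
        pts = rng.normal(0, 1, (30, 5))
        pts[10:20] += 6.0
        a = gap_statistic(make_slea(pts), k_max=5, n_ref=20, seed=3)
        b = gap_statistic(make_slea(pts[:, ::-1]), k_max=5, n_ref=20, seed=3)
        assert a.chosen_k == b.chosen_k

    def test_reproducible_for_fixed_seed(self, rng):
        pts = rng.normal(0, 1, (25, 3))
        a = gap_statistic(make_slea(pts), k_max=4, n_ref=15, seed=9)
        b = gap_statistic(make_slea(pts), k_max=4, n_ref=15, seed=9)
        assert np.array_equal(a.gap, b.gap)
        assert np.array_equal(a.se, b.se)


class TestLabelEndotypes:
    def _three_cluster_slea(self):
        sets = [
            "HALLMARK_INFLAMMATORY_RESPONSE",
            "HALLMARK_COMPLEMENT",
            "HALLMARK_IL6_JAK_STAT3_SIGNALING",
            "HALLMARK_TNFA_SIGNALING_VIA_NFKB",
        ]
        scores = np.repeat([-1.0, 0.0, 1.0], 3)
        z = np.tile(scores, (4, 1))
        slea = make_slea(z.T, feature_names=sets)
        clusters = pd.Series(
            np.repeat([2, 3, 1], 3), index=slea.zscores.columns, name="cluster"
        )
        return slea, clusters

    def test_labels_follow_score_ranking_not_cluster_ids(self):
        slea, clusters = self._three_cluster_slea()
        asn = label_endotypes(clusters, slea)
        by_cluster = asn.assignments.groupby("cluster")["endotype"].first()
        assert by_cluster[2] == "inflam.lo"
        assert by_cluster[3] == "inflam.mid"
        assert by_cluster[1] == "inflam.hi"

    def test_relabeling_cluster_ids_keeps_endotypes(self):
        slea, clusters = self._three_cluster_slea()
        a = label_endotypes(clusters, slea).assignments["endotype"]
        remap = {1: 7, 2: 5, 3: 9}
        b = label_endotypes(clusters.map(remap), slea).assignments["endotype"]
        assert (a == b).all()

    def test_tertile_cut_of_1_to_9(self):
        sets = [
            "HALLMARK_INFLAMMATORY_RESPONSE",
            "HALLMARK_COMPLEMENT",
            "HALLMARK_IL6_JAK_STAT3_SIGNALING",
            "HALLMARK_TNFA_SIGNALING_VIA_NFKB",
        ]
        scores = np.arange(1.0, 10.0)
        slea = make_slea(np.tile(scores, (4, 1)).T, feature_names=sets)
        clusters = pd.Series(
            np.repeat([1, 2, 3], 3), index=slea.zscores.columns, name="cluster"
        )
        asn = label_endotypes(clusters, slea)
        tert = asn.assignments["tertile"].tolist()
        assert tert == ["low"] * 3 + ["mid"] * 3 + ["high"] * 3

    def test_wrong_k_rejected(self):
        slea, clusters = self._three_cluster_slea()
        clusters2 = clusters.copy()
        clusters2.iloc[:] = 1
        with pytest.raises(ValueError, match="3 clusters"):
            label_endotypes(clusters2, slea)

    def test_missing_inflammatory_set_rejected(self):
        slea, clusters = self._three_cluster_slea()
        with pytest.raises(KeyError):
            label_endotypes(clusters, slea, inflammatory_sets=("NOT_A_SET",) * 4)


class TestTemporalStability:
    def _meta(self, participants, days):
        sids = [f"{p}_d{d}" for p, d in zip(participants, days)]
        return (
            pd.DataFrame(
                {
                    "participant_id": participants,
                    "study_id": "st",
                    "platform": "pf",
                    "sample_type": "pbmc",
                    "vaccine": "v",
                    "day": days,
                },
                index=pd.Index(sids, name="sample_id"),
            ),
            sids,
        )

    def test_participant_constant_scores_give_stability_one(self):
        participants = ["p1", "p1", "p2", "p2", "p3", "p3"]
        days = [-7, 0, -7, 0, -7, 0]
        meta, sids = self._meta(participants, days)
        values = np.array([[1.0, 1.0, 2.0, 2.0, 3.0, 3.0]])
        slea = make_slea(values.T, sample_ids=sids, feature_names=["S"])
        per_set, aggregate = temporal_stability(slea, meta)
        assert per_set["S"] == pytest.approx(1.0)
        assert aggregate == pytest.approx(1.0)

    def test_iid_scores_give_near_zero_stability(self, rng):
        n_part, n_rep = 50, 3
        participants = [f"p{i}" for i in range(n_part) for _ in range(n_rep)]
        days = [-7, 0, 70] * n_part
        meta, sids = self._meta(participants, days)
        values = rng.normal(0, 1, (len(sids), 2))
        slea = make_slea(values, sample_ids=sids, feature_names=["S1", "S2"])
        _, aggregate = temporal_stability(slea, meta)
        assert aggregate <= 0.1

    def test_only_eligible_days_enter(self, rng):
        # day-7 (post) samples carry huge deviations but are ineligible
        participants = ["p1", "p1", "p1", "p2", "p2", "p2"]
        days = [0, 70, 7, 0, 70, 7]
        meta, sids = self._meta(participants, days)
        values = np.array([[1.0, 1.0, 99.0, 2.0, 2.0, -99.0]])
        slea = make_slea(values.T, sample_ids=sids, feature_names=["S"])
        per_set, _ = temporal_stability(slea, meta)
        assert per_set["S"] == pytest.approx(1.0)

    def test_no_repeated_samples_rejected(self):
        participants = ["p1", "p2", "p3"]
        days = [0, 0, 0]
        meta, sids = self._meta(participants, days)
        slea = make_slea(np.zeros((3, 1)), sample_ids=sids, feature_names=["S"])
        with pytest.raises(ValueError, match="repeated"):
            temporal_stability(slea, meta)


class TestParticipantConsensus:
    def test_majority_label_wins(self):
        sets = [
            "HALLMARK_INFLAMMATORY_RESPONSE",
            "HALLMARK_COMPLEMENT",
            "HALLMARK_IL6_JAK_STAT3_SIGNALING",
            "HALLMARK_TNFA_SIGNALING_VIA_NFKB",
        ]
        scores = np.array([-1.0, -1.0, 0.0, 0.0, 1.0, 1.0, 1.0, -1.0])
        slea = make_slea(np.tile(scores, (4, 1)).T, feature_names=sets)
        clusters = pd.Series(
            [1, 1, 2, 2, 3, 3, 3, 1], index=slea.zscores.columns, name="cluster"
        )
        asn = label_endotypes(clusters, slea)
        meta = pd.DataFrame(
            {"participant_id": ["a", "a", "b", "b", "c", "c", "c", "c"]},
            index=slea.zscores.columns,
        )
        consensus = asn.participant_consensus(meta)
        assert consensus["a"] == "inflam.lo"
        assert consensus["b"] == "inflam.mid"
        assert consensus["c"] == "inflam.hi"  # 3 hi samples vs 1 lo
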