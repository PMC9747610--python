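"""Post-vaccination gene-set kinetics stratified by endotype.

Per participant and superset, the change from the pre-vaccination SLEA score
to the score in each post-vaccination day bin is computed; endotype groups
are compared per (superset, bin) with the Wilcoxon rank-sum test, and p
values are Benjamini-Hochberg adjusted across the whole table.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from vaxendo.slea import SleaMatrix
from vaxendo.stats import bh_adjust, wilcoxon_rank_sum

logger = logging.getLogger(__name__)

#: Default day bins: (label, center, tolerance). The last bin is open-ended.
DEFAULT_DAY_BINS = (
    ("day1", 1, 1),
    ("day3", 3, 1),
    ("day7", 7, 2),
    ("day14", 14, 2),
    ("day21+", 21, None),
)

DEFAULT_PAIRS = (
    ("inflam.hi", "inflam.lo"),
    ("inflam.hi", "inflam.mid"),
    ("inflam.mid", "inflam.lo"),
)


def _bin_days(center: int, tolerance: int | None, days: np.ndarray) -> np.ndarray:
    if tolerance is None:
        return days[days >= center]
    return days[np.abs(days - center) <= tolerance]


def compute_deltas(
    slea: SleaMatrix,
    samples: pd.DataFrame,
    endotype_of_participant: pd.Series,
    day_bins=DEFAULT_DAY_BINS,
) -> pd.DataFrame:
    """Per-participant change of each superset score from pre-vaccination.

    The baseline is the day-0 sample (day -7 fallback); the post sample in a
    bin is the one nearest the bin center (ties to the later day).
    Participants lacking a baseline or an in-bin sample are omitted and
    logged. Returns tidy rows (participant_id, endotype, superset, day_bin,
    delta).
    """
    meta = samples.loc[samples.index.intersection(slea.zscores.columns)]
    rows = []
    for pid, grp in meta.groupby("participant_id", sort=False):
        if pid not in endotype_of_participant.index:
            logger.info("participant %s omitted from kinetics: no endotype label", pid)
            continue
        by_day = grp.sort_index().groupby("day").groups
        if 0 in by_day:
            base_ids = by_day[0]
        elif -7 in by_day:
            base_ids = by_day[-7]
        else:
            logger.info("participant %s omitted from kinetics: no pre-vaccination sample", pid)
            continue
        baseline = slea.zscores[list(base_ids)].mean(axis=1)
        days = np.array([d for d in by_day if d > 0])
        for label, center, tol in day_bins:
            in_bin = _bin_days(center, tol, days)
            if len(in_bin) == 0:
                continue
            dist = np.abs(in_bin - center)
            day_star = int(in_bin[dist == dist.min()].max())
            post = slea.zscores[list(by_day[day_star])].mean(axis=1)
            delta = post - baseline
            for superset, value in delta.items():
                rows.append(
                    {
                        "participant_id": pid,
                        "endotype": endotype_of_participant[pid],
                        "superset": superset,
                        "day_bin": label,
                        "delta": float(value),
                    }
                )
    return pd.DataFrame(rows)


def compare_endotypes(deltas: pd.DataFrame, pairs=DEFAULT_PAIRS) -> pd.DataFrame:
    """Wilcoxon rank-sum comparisons of participant deltas between endotypes.

    The effect size is the difference of group medians (A - B). P values are
    BH-adjusted across all (superset, day_bin, pair) tests in the table;
    comparisons with fewer than 2 participants in a group are skipped and
    logged.
    """
    rows = []
    for (superset, day_bin), grp in deltas.groupby(["superset", "day_bin"], sort=False):
        for a, b in pairs:
            da = grp.loc[grp["endotype"] == a, "delta"].to_numpy()
            db = grp.loc[grp["endotype"] == b, "delta"].to_numpy()
            if len(da) < 2 or len(db) < 2:
                logger.info(
                    "comparison %s vs %s skipped for %s/%s: group too small",
                    a, b, superset, day_bin,
                )
                continue
            res = wilcoxon_rank_sum(da, db)
            rows.append(
                {
                    "superset": superset,
                    "day_bin": day_bin,
                    "endotype_pair": f"{a} vs {b}",
                    "n_a": len(da),
                    "n_b": len(db),
                    "effect": float(np.median(da) - np.median(db)),
                    "wilcoxon_p": res.p_value,
                }
            )
    out = pd.DataFrame(rows)
    if not out.empty:
        out["bh_adjusted_p"] = bh_adjust(out["wilcoxon_p"].to_numpy())
    return out


def summarize_kinetics(deltas: pd.DataFrame) -> pd.DataFrame:
    """Median participant delta per (superset, day bin, endotype)."""
    if deltas.empty:
        return pd.DataFrame(
            columns=["superset", "day_bin", "endotype", "n_participants", "median_delta"]
        )
    return (
        deltas.groupby(["superset", "day_bin", "endotype"], sort=False)["delta"]
        .agg(n_participants="size", median_delta="median")
        .reset_index()
    )
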