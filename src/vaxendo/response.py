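"""Antibody maximum fold change (MFC) and responder classification.

The response metric is the maximum, over the vaccine's strains, of the
day-28 (+/- 2 d) to pre-vaccination titer ratio. Because titer scales differ
across assays and vaccines, the MFC is z-scaled within vaccine for pooled
displays, and high/low responders are called per study at the 70th/30th
percentiles of the study's MFC distribution.
"""

from __future__ import annotations

import logging
import os

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

TITER_COLUMNS = ("participant_id", "study_id", "vaccine", "strain", "day", "titer")
TARGET_DAY = 28
WINDOW = 2
#: Minimum participants per study for percentile-based responder calls.
MIN_STUDY_SIZE = 3


def load_titers(path: str | os.PathLike) -> pd.DataFrame:
    """Load and validate a titer TSV (participant x strain x day rows)."""
    df = pd.read_csv(path, sep="\t")
    return validate_titers(df)


def validate_titers(titers: pd.DataFrame) -> pd.DataFrame:
    """Check the titer-table invariants: positive titers, unique triplets."""
    missing = [c for c in TITER_COLUMNS if c not in titers.columns]
    if missing:
        raise ValueError(f"titer table missing columns: {missing}")
    if (titers["titer"] <= 0).any():
        bad = titers.loc[titers["titer"] <= 0].head(5)
        raise ValueError(f"titers must be > 0; offenders:\n{bad}")
    dup = titers.duplicated(subset=["participant_id", "strain", "day"])
    if dup.any():
        raise ValueError(
            f"duplicate (participant, strain, day) rows: "
            f"{titers.loc[dup, ['participant_id', 'strain', 'day']].head(5).to_dict('records')}"
        )
    return titers


def _pick_post_day(days: np.ndarray, target: int, window: int) -> int | None:
    """In-window day nearest the target; ties broken toward the later day."""
    in_window = days[np.abs(days - target) <= window]
    if len(in_window) == 0:
        return None
    dist = np.abs(in_window - target)
    best = in_window[dist == dist.min()]
    return int(best.max())


def compute_mfc(
    titers: pd.DataFrame, target_day: int = TARGET_DAY, window: int = WINDOW
) -> pd.DataFrame:
    """Per-participant maximum fold change of any strain at day 28 (+/- 2 d).

    The pre-vaccination titer is the day-0 value, falling back to day -7;
    the post titer is the in-window day nearest the target (ties to the
    later day). Participants lacking a strain with both titers are omitted
    and logged. Returns one row per participant with columns mfc, log2_mfc,
    day_used, study_id, vaccine.
    """
    validate_titers(titers)
    rows = []
    for pid, grp in titers.groupby("participant_id", sort=False):
        fcs = {}
        day_used = None
        for strain, sg in grp.groupby("strain", sort=False):
            by_day = sg.set_index("day")["titer"]
            if 0 in by_day.index:
                baseline = float(by_day.loc[0])
            elif -7 in by_day.index:
                baseline = float(by_day.loc[-7])
            else:
                continue
            post_days = by_day.index[by_day.index > 0].to_numpy()
            day_star = _pick_post_day(post_days, target_day, window)
            if day_star is None:
                continue
            fcs[strain] = float(by_day.loc[day_star]) / baseline
            day_used = day_star
        if not fcs:
            logger.info("participant %s omitted: no strain with baseline and in-window titers", pid)
            continue
        rows.append(
            {
                "participant_id": pid,
                "study_id": grp["study_id"].iloc[0],
                "vaccine": grp["vaccine"].iloc[0],
                "mfc": max(fcs.values()),
                "log2_mfc": float(np.log2(max(fcs.values()))),
                "day_used": day_used,
            }
        )
    return pd.DataFrame(rows).set_index("participant_id")


def scale_mfc(responses: pd.DataFrame) -> pd.DataFrame:
    """Z-scale log2 MFC to mean 0 / sd 1 within each vaccine.

    Single-participant vaccines get a missing scaled value; a zero
    within-vaccine sd yields scaled 0; both are logged.
    """
    out = responses.copy()
    scaled = pd.Series(np.nan, index=out.index, dtype=float)
    for vaccine, grp in out.groupby("vaccine"):
        if len(grp) < 2:
            logger.warning("vaccine %r has a single participant; scaled MFC set missing", vaccine)
            continue
        sd = grp["log2_mfc"].std(ddof=1)
        if sd == 0:
            logger.warning("vaccine %r has zero MFC variance; scaled MFC set to 0", vaccine)
            scaled.loc[grp.index] = 0.0
        else:
            scaled.loc[grp.index] = (grp["log2_mfc"] - grp["log2_mfc"].mean()) / sd
    out["scaled_mfc"] = scaled
    return out


def discretize_responders(responses: pd.DataFrame) -> pd.DataFrame:
    """Call high/moderate/low responders per study at the 70th/30th percentiles.

    Thresholds are Hyndman-Fan type-7 quantiles of the study's MFC values:
    high responders have MFC >= the 70th percentile, low responders MFC <=
    the 30th, everyone strictly between is moderate. A participant at or
    beyond both thresholds simultaneously (degenerate all-equal case) is
    moderate. Studies below 3 participants are all moderate, with a warning.
    """
    out = responses.copy()
    responder = pd.Series("moderate", index=out.index, dtype=object)
    for study, grp in out.groupby("study_id"):
        if len(grp) < MIN_STUDY_SIZE:
            logger.warning(
                "study %r has %d participants (< %d); all called moderate",
                study, len(grp), MIN_STUDY_SIZE,
            )
            continue
        p30, p70 = np.quantile(grp["mfc"].to_numpy(), [0.30, 0.70])
        is_high = grp["mfc"] >= p70
        is_low = grp["mfc"] <= p30
        both = is_high & is_low
        responder.loc[grp.index[is_high & ~both]] = "high"
        responder.loc[grp.index[is_low & ~both]] = "low"
    out["responder"] = responder
    out.attrs["quantile_convention"] = "Hyndman-Fan type 7"
    return out
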