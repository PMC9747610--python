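"""Bacterial/viral etiology metascore.

A seven-gene classifier of inflammation etiology: the mean log2 expression
of four bacterial-infection markers (HK3, TNIP1, GPAA1, CTSB) minus the mean
of three viral-infection markers (IFI27, JUP, LAX1). Scores at or above 0
are called bacterial-like, below 0 viral-like. Intended to run on
batch-corrected log2 expression.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from vaxendo.compendium import Compendium

BACTERIAL_GENES = ("HK3", "TNIP1", "GPAA1", "CTSB")
VIRAL_GENES = ("IFI27", "JUP", "LAX1")


@dataclass
class MetascoreResult:
    """Per-sample metascore and bacterial/viral call.

    ``call`` is bacterial_like iff score >= 0.
    """

    score: pd.Series
    call: pd.Series
    genes_used: tuple[str, ...]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"score": self.score, "call": self.call})


def bacterial_viral_score(compendium: Compendium) -> MetascoreResult:
    """Compute the seven-gene bacterial/viral metascore per sample.

    score(s) = mean(HK3, TNIP1, GPAA1, CTSB) - mean(IFI27, JUP, LAX1).
    All seven genes must be present; there is no partial scoring.
    """
    genes = set(compendium.expression.index)
    missing = [g for g in BACTERIAL_GENES + VIRAL_GENES if g not in genes]
    if missing:
        raise KeyError(f"metascore genes absent from the matrix: {missing}")
    expr = compendium.expression
    score = expr.loc[list(BACTERIAL_GENES)].mean(axis=0) - expr.loc[list(VIRAL_GENES)].mean(axis=0)
    score.name = "metascore"
    call = pd.Series(
        ["bacterial_like" if s >= 0 else "viral_like" for s in score],
        index=score.index,
        name="call",
    )
    return MetascoreResult(score=score, call=call, genes_used=BACTERIAL_GENES + VIRAL_GENES)
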