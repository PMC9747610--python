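"""Within-study quantile normalization and cross-study batch correction.

Batch effects (platform, study, blood sample type) are estimated by per-gene
ordinary least squares on pre-vaccination samples only (day -7 and day 0) and
the estimated effects are subtracted from all samples, before and after
vaccination, so that post-vaccination kinetics are corrected with the same
offsets that were learned where no vaccine response is present.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from vaxendo.compendium import Compendium

logger = logging.getLogger(__name__)

#: Factors entering the batch model, in the order their design columns are
#: preferred when the design is rank-deficient: columns of later factors are
#: dropped first, so study (the finer factor) absorbs confounded variance and
#: platform columns are dropped before study columns.
BATCH_FACTORS = ("study_id", "sample_type", "platform")


def quantile_normalize_within_study(compendium: Compendium) -> Compendium:
    """Quantile-normalize each study's samples to their common mean distribution.

    Within each study, every sample's sorted values are replaced by the
    across-sample mean of order statistics, so all columns become permutations
    of one common vector. Tied input values receive the mean of the normalized
    values at their tied ranks. Single-sample studies are returned unchanged.
    """
    expr = compendium.expression.copy()
    values = expr.to_numpy(dtype=float)
    for study, meta in compendium.samples.groupby("study_id", sort=False):
        cols = [expr.columns.get_loc(s) for s in meta.index]
        if len(cols) < 2:
            continue
        block = values[:, cols]
        order = np.sort(block, axis=0)
        ref = order.mean(axis=1)
        for j in range(block.shape[1]):
            col = block[:, j]
            ranks = np.argsort(np.argsort(col, kind="stable"), kind="stable")
            normalized = ref[ranks]
            # tie convention: tied inputs get the mean of ref at their tied ranks
            uniq, inverse, counts = np.unique(col, return_inverse=True, return_counts=True)
            if len(uniq) < len(col):
                sums = np.bincount(inverse, weights=normalized)
                normalized = (sums / counts)[inverse]
            block[:, j] = normalized
        values[:, cols] = block
    expr.iloc[:, :] = values
    return Compendium(expression=expr, samples=compendium.samples.copy(), gene_sets=compendium.gene_sets)


@dataclass
class BatchModel:
    """Per-gene linear batch-effect model estimated on pre-vaccination samples.

    ``coefficients`` holds one row per gene and one column per retained design
    column (intercept first); ``columns`` are (factor, level) design labels;
    ``aliased`` lists design columns dropped for rank deficiency, in drop
    order; ``reference_levels`` records each factor's reference level and
    ``omitted_factors`` any single-level factor silently excluded.
    """

    coefficients: pd.DataFrame
    columns: list[tuple[str, str]]
    aliased: list[tuple[str, str]] = field(default_factory=list)
    reference_levels: dict[str, str] = field(default_factory=dict)
    omitted_factors: list[str] = field(default_factory=list)

    def design_matrix(self, samples: pd.DataFrame) -> np.ndarray:
        """Build the retained design (without intercept) for arbitrary samples."""
        cols = []
        for factor, level in self.columns:
            observed = set(samples[factor].astype(str))
            known = {lvl for f, lvl in self.columns if f == factor}
            known.add(self.reference_levels[factor])
            unseen = observed - known
            if unseen:
                raise ValueError(
                    f"factor {factor!r} has levels unseen at fit time: {sorted(unseen)}"
                )
            cols.append((samples[factor].astype(str) == level).to_numpy(dtype=float))
        if not cols:
            return np.empty((len(samples), 0))
        return np.column_stack(cols)


def _build_design(samples: pd.DataFrame) -> tuple[np.ndarray, list[tuple[str, str]], list[tuple[str, str]], dict[str, str], list[str]]:
    """Treatment-coded design with deterministic aliased-column dropping."""
    candidate_cols: list[tuple[str, str]] = []
    reference: dict[str, str] = {}
    omitted: list[str] = []
    for factor in BATCH_FACTORS:
        levels = sorted(samples[factor].astype(str).unique())
        if len(levels) < 2:
            omitted.append(factor)
            logger.info("batch factor %r has a single level; omitted", factor)
            continue
        reference[factor] = levels[0]
        candidate_cols += [(factor, lvl) for lvl in levels[1:]]

    n = len(samples)
    kept: list[tuple[str, str]] = []
    aliased: list[tuple[str, str]] = []
    basis = [np.ones(n)]
    current = np.ones((n, 1))
    for factor, level in candidate_cols:
        col = (samples[factor].astype(str) == level).to_numpy(dtype=float)
        trial = np.column_stack([current, col])
        if np.linalg.matrix_rank(trial) > current.shape[1]:
            kept.append((factor, level))
            current = trial
        else:
            aliased.append((factor, level))
            logger.info("design column %s=%s aliased; dropped", factor, level)
    X = current  # includes intercept as first column
    return X, kept, aliased, reference, omitted


def fit_batch_model(compendium: Compendium) -> BatchModel:
    """Fit per-gene OLS of expression on platform, study and sample type.

    Only pre-vaccination samples (day -7/0) enter the fit. Rank-deficient
    designs (e.g. platform nested in study) are resolved by dropping aliased
    columns deterministically: candidate columns are scanned in the order
    study, sample type, platform, so platform columns are dropped before study
    columns; dropped columns are recorded on the model.
    """
    pre = compendium.samples[compendium.prevaccination_mask()]
    if len(pre) < 2:
        raise ValueError("need >=2 pre-vaccination samples (day -7/0) to fit the batch model")
    X, kept, aliased, reference, omitted = _build_design(pre)
    Y = compendium.expression[pre.index].to_numpy(dtype=float).T  # samples x genes
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    coef = pd.DataFrame(
        beta.T,
        index=compendium.expression.index,
        columns=["intercept"] + [f"{f}:{lvl}" for f, lvl in kept],
    )
    return BatchModel(
        coefficients=coef,
        columns=kept,
        aliased=aliased,
        reference_levels=reference,
        omitted_factors=omitted,
    )


def apply_batch_correction(compendium: Compendium, model: BatchModel) -> Compendium:
    """Subtract the estimated batch component from every sample (all days).

    The per-gene intercept is retained, so the grand expression level is
    preserved; only the factor-level offsets are removed. Samples with a
    factor level unseen at fit time raise an error.
    """
    X = model.design_matrix(compendium.samples)  # samples x kept-cols
    beta = model.coefficients.iloc[:, 1:].to_numpy(dtype=float)  # genes x kept-cols
    corrected = compendium.expression.to_numpy(dtype=float) - beta @ X.T
    expr = pd.DataFrame(
        corrected, index=compendium.expression.index, columns=compendium.expression.columns
    )
    return Compendium(expression=expr, samples=compendium.samples.copy(), gene_sets=compendium.gene_sets)
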