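"""Principal variance component analysis (PVCA).

Attributes transcriptome variance to categorical sample factors: principal
components of the sample-sample covariance of gene-standardized expression
are each decomposed into per-factor variance components (all factors fitted
jointly as random effects), components are truncated at zero, normalized per
component and averaged with eigenvalue weights. Uncertainty comes from a
participant-level bootstrap with percentile confidence intervals.

The variance-component estimator is a Haseman-Elston-style method of
moments: for each component score y (centered), the products y_i * y_j are
regressed on same-level indicators of every factor plus the diagonal
(residual) indicator. It is deterministic, has no convergence failures on
null components, and is unbiased for balanced designs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from vaxendo.compendium import Compendium

#: Day values above this are collapsed into one category when encoding time.
DAY_CENSOR = 20
MISSING_LEVEL = "missing"


def encode_factors(samples: pd.DataFrame, factors: list[str]) -> pd.DataFrame:
    """Encode metadata columns as categorical factors for PVCA.

    Age is binned into 10-year intervals ("20-29", "30-39", ...); day values
    above 20 collapse into a single ">=20" category while earlier days stay
    distinct; missing values become an explicit "missing" level.
    """
    out = {}
    for col in factors:
        if col not in samples.columns:
            raise KeyError(f"unknown metadata column {col!r}")
        s = samples[col]
        if col == "age_years":
            num = pd.to_numeric(s, errors="coerce")
            lo = (np.floor(num / 10) * 10).astype("Int64")
            enc = lo.map(lambda v: MISSING_LEVEL if pd.isna(v) else f"{v}-{v + 9}")
        elif col == "day":
            num = pd.to_numeric(s, errors="coerce")
            enc = num.map(
                lambda v: MISSING_LEVEL
                if pd.isna(v)
                else (f">={DAY_CENSOR}" if v > DAY_CENSOR else str(int(v)))
            )
        else:
            enc = s.astype(str).replace({"nan": MISSING_LEVEL, "NA": MISSING_LEVEL, "": MISSING_LEVEL})
            enc = enc.where(~s.isna(), MISSING_LEVEL)
        out[col] = enc.astype(str)
    return pd.DataFrame(out, index=samples.index)


@dataclass
class PvcaResult:
    """Variance fractions per factor (plus ``resid``) with bootstrap CIs.

    ``fractions`` is the full-data point estimate (sums to 1); ``boot_mean``
    and ``ci`` (2.5/97.5 percentiles) summarize ``n_bootstrap``
    participant-level resamples. ``pc_weights`` are the eigenvalue shares of
    the retained components.
    """

    fractions: dict[str, float]
    boot_mean: dict[str, float]
    ci: dict[str, tuple[float, float]]
    n_pcs: int
    pc_weights: np.ndarray
    n_bootstrap: int
    cumvar_threshold: float
    day_censor_note: str = f"day values > {DAY_CENSOR} collapsed into one '>= {DAY_CENSOR}' category"

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for f, frac in self.fractions.items():
            lo, hi = self.ci.get(f, (np.nan, np.nan))
            rows.append(
                {
                    "factor": f,
                    "fraction": frac,
                    "boot_mean": self.boot_mean.get(f, np.nan),
                    "ci_low": lo,
                    "ci_high": hi,
                }
            )
        return pd.DataFrame(rows)


def _standardize_genes(values: np.ndarray) -> np.ndarray:
    mean = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, ddof=1, keepdims=True)
    sd[sd == 0] = 1.0
    return (values - mean) / sd


def _retained_pcs(z: np.ndarray, threshold: float) -> tuple[np.ndarray, np.ndarray]:
    """Eigenvectors (sample scores) and eigenvalues reaching the cumvar threshold."""
    n = z.shape[1]
    cov = (z.T @ z) / max(z.shape[0] - 1, 1)
    eigval, eigvec = np.linalg.eigh(cov)
    order = np.argsort(eigval)[::-1]
    eigval = np.clip(eigval[order], 0.0, None)
    eigvec = eigvec[:, order]
    total = eigval.sum()
    if total == 0:
        return eigvec[:, :1], eigval[:1]
    cum = np.cumsum(eigval) / total
    k = int(np.searchsorted(cum, threshold) + 1)
    k = min(k, n)
    return eigvec[:, :k], eigval[:k]


def _he_components(
    y: np.ndarray, same_level: list[np.ndarray], exclude: np.ndarray | None = None
) -> np.ndarray:
    """Joint method-of-moments variance components for one PC score vector.

    Because gene standardization centers every gene across samples, the PC
    score vectors live in the subspace orthogonal to the all-ones vector;
    the moment design therefore uses the correspondingly centered indicator
    matrices M S_f M (M = I - 11'/n), which removes the attenuation the
    centering would otherwise induce on same-level products. ``exclude``
    masks sample pairs whose products are degenerate (bootstrap copies of
    one original sample share their noise draw and would otherwise read as
    factor covariance). Returns one non-negative component per factor plus
    the residual (last).
    """
    yc = y - y.mean()
    prod = np.outer(yc, yc)
    n = len(y)
    iu = np.triu_indices(n)
    response = prod[iu]

    def _center(s: np.ndarray) -> np.ndarray:
        row = s.mean(axis=1, keepdims=True)
        col = s.mean(axis=0, keepdims=True)
        return s - row - col + s.mean()

    design = np.column_stack(
        [_center(s)[iu] for s in same_level] + [_center(np.eye(n))[iu]]
    )
    if exclude is not None:
        keep = ~exclude[iu]
        design, response = design[keep], response[keep]
    comps, *_ = np.linalg.lstsq(design, response, rcond=None)
    return np.clip(comps, 0.0, None)


def _pvca_point(
    values: np.ndarray,
    encoded: pd.DataFrame,
    factors: list[str],
    threshold: float,
    origin: np.ndarray | None = None,
) -> dict[str, float]:
    z = _standardize_genes(values)
    pcs, eigval = _retained_pcs(z, threshold)
    same_level = []
    for f in factors:
        codes = pd.Categorical(encoded[f]).codes
        same_level.append((codes[:, None] == codes[None, :]).astype(float))
    exclude = None
    if origin is not None:
        exclude = (origin[:, None] == origin[None, :]) & ~np.eye(len(origin), dtype=bool)
    weights = eigval / eigval.sum() if eigval.sum() > 0 else np.ones_like(eigval) / len(eigval)
    fractions = np.zeros(len(factors) + 1)
    for i in range(pcs.shape[1]):
        comps = _he_components(pcs[:, i], same_level, exclude=exclude)
        total = comps.sum()
        if total == 0:
            per_pc = np.zeros_like(comps)
            per_pc[-1] = 1.0
        else:
            per_pc = comps / total
        fractions += weights[i] * per_pc
    names = factors + ["resid"]
    return dict(zip(names, fractions.tolist()))


def pvca(
    compendium: Compendium,
    factors: list[str],
    cumvar_threshold: float = 0.60,
    n_bootstrap: int = 0,
    seed: int = 0,
    extra_factors: pd.DataFrame | None = None,
) -> PvcaResult:
    """Estimate per-factor variance fractions of the expression matrix.

    Parameters
    ----------
    factors
        Metadata columns to attribute variance to; encoded via
        :func:`encode_factors`. Columns of ``extra_factors`` (indexed by
        sample id, already categorical) may also be named.
    cumvar_threshold
        Retain the smallest leading set of principal components whose
        eigenvalues reach this cumulative-variance share (default 0.60).
    n_bootstrap
        Participant-level bootstrap replicates for the confidence intervals;
        0 skips the bootstrap (point estimate only).
    """
    samples = compendium.samples
    if extra_factors is not None:
        samples = samples.join(extra_factors)
    if len(samples) < 2:
        raise ValueError("PVCA needs >=2 samples")
    if not factors:
        raise ValueError("PVCA needs >=1 factor")
    meta_cols = [f for f in factors if f in samples.columns]
    missing = set(factors) - set(meta_cols)
    if missing:
        raise KeyError(f"unknown factor columns: {sorted(missing)}")
    encoded = encode_factors(samples, factors)
    n = len(samples)
    for f in factors:
        if encoded[f].nunique() >= n:
            raise ValueError(
                f"factor {f!r} has as many levels as samples; unidentifiable, remove it"
            )

    values = compendium.expression.to_numpy(dtype=float)
    point = _pvca_point(values, encoded, factors, cumvar_threshold)
    z = _standardize_genes(values)
    _, eigval = _retained_pcs(z, cumvar_threshold)

    names = factors + ["resid"]
    boot_mean = dict(point)
    ci = {f: (point[f], point[f]) for f in names}
    if n_bootstrap > 0:
        rng = np.random.default_rng(seed)
        participants = samples["participant_id"].to_numpy()
        unique_parts = pd.unique(participants)
        col_of_part = {p: np.flatnonzero(participants == p) for p in unique_parts}
        replicates = np.zeros((n_bootstrap, len(names)))
        for b in range(n_bootstrap):
            drawn = rng.choice(unique_parts, size=len(unique_parts), replace=True)
            cols = np.concatenate([col_of_part[p] for p in drawn])
            frac = _pvca_point(
                values[:, cols], encoded.iloc[cols], factors, cumvar_threshold, origin=cols
            )
            replicates[b] = [frac[f] for f in names]
        boot_mean = dict(zip(names, replicates.mean(axis=0).tolist()))
        lo = np.percentile(replicates, 2.5, axis=0)
        hi = np.percentile(replicates, 97.5, axis=0)
        ci = {f: (float(lo[i]), float(hi[i])) for i, f in enumerate(names)}

    return PvcaResult(
        fractions=point,
        boot_mean=boot_mean,
        ci=ci,
        n_pcs=len(eigval),
        pc_weights=eigval / eigval.sum() if eigval.sum() > 0 else eigval,
        n_bootstrap=n_bootstrap,
        cumvar_threshold=cumvar_threshold,
    )
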