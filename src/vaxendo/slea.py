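"""Sample-level enrichment analysis (SLEA).

For each gene set and sample, the observed mean of the set's standardized
expression is compared against a null of equal-size random gene sets drawn
from the whole matrix; the z-score of the observed mean against that null is
the set's activity in the sample. Member-set z-scores are averaged into the
seven cell-subset / pathway supersets.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import comb

from vaxendo.compendium import Compendium, GeneSetCollection, SUPERSET_LABELS

logger = logging.getLogger(__name__)

#: Default minimum effective set size (genes found in the matrix).
MIN_SET_SIZE = 5


@dataclass
class SleaMatrix:
    """Gene-set x sample z-score matrix with provenance.

    ``effective_size`` maps each retained set to the number of its genes
    present in the expression matrix; ``n_permutations`` is 0 when the null
    was fully enumerated.
    """

    zscores: pd.DataFrame
    effective_size: dict[str, int]
    n_permutations: int
    seed: int
    dropped_sets: list[str]

    @property
    def sample_ids(self) -> pd.Index:
        return self.zscores.columns


def _standardize(values: np.ndarray) -> np.ndarray:
    mean = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, ddof=1, keepdims=True)
    out = np.zeros_like(values)
    np.divide(values - mean, sd, out=out, where=sd != 0)
    return out


def _null_moments(
    z: np.ndarray, m: int, n_permutations: int, rng: np.random.Generator, exact: bool
) -> tuple[np.ndarray, np.ndarray, bool]:
    """Per-sample mean and sd of random size-m set means.

    When ``exact`` (or when all subsets are fewer than the requested draws)
    the null is fully enumerated; otherwise ``n_permutations`` random size-m
    subsets are drawn without replacement and shared across all samples.
    Standard deviations are over the null ensemble (ddof=0).
    """
    n_genes = z.shape[0]
    n_subsets = comb(n_genes, m, exact=True)
    if exact or n_subsets <= n_permutations:
        idx = np.array(list(itertools.combinations(range(n_genes), m)))
        enumerated = True
    else:
        idx = np.argsort(rng.random((n_permutations, n_genes)), axis=1)[:, :m]
        enumerated = False
    null_means = z[idx].mean(axis=1)  # draws x samples
    return null_means.mean(axis=0), null_means.std(axis=0, ddof=0), enumerated


def slea_zscores(
    compendium: Compendium,
    gene_sets: GeneSetCollection | None = None,
    n_permutations: int = 1000,
    seed: int = 0,
    min_set_size: int = MIN_SET_SIZE,
    exact: bool = False,
    standardize: bool = True,
) -> SleaMatrix:
    """Per-sample gene-set activity z-scores against a random-set null.

    Expression is gene-standardized internally (each gene centered and scaled
    across samples). For a set of effective size m, the observed statistic in
    sample s is the mean standardized expression of the set's genes; the null
    is the distribution of means of random m-gene subsets of the matrix (one
    shared block of draws per distinct m, so equal-size sets face an
    identical null). ``exact=True`` enumerates all subsets instead of
    sampling; a null sd of 0 defines z = 0. Sets matching fewer than
    ``min_set_size`` genes are dropped and logged.

    After (optional) gene standardization, scoring is strictly within-sample:
    a sample's z-scores depend only on its own column of the scored matrix.
    """
    gene_sets = gene_sets or compendium.gene_sets
    if gene_sets is None or len(gene_sets) == 0:
        raise ValueError("no gene sets supplied")
    if not exact and n_permutations < 100:
        raise ValueError("n_permutations must be >= 100 (or use exact=True)")

    z = compendium.expression.to_numpy(dtype=float)
    if standardize:
        z = _standardize(z)
    gene_index = {g: i for i, g in enumerate(compendium.expression.index)}

    members: dict[str, np.ndarray] = {}
    dropped: list[str] = []
    for name, genes in gene_sets.sets.items():
        idx = np.array([gene_index[g] for g in genes if g in gene_index], dtype=int)
        if len(idx) < max(min_set_size, 1):
            dropped.append(name)
            logger.warning(
                "gene set %r dropped: %d of %d genes matched (< %d)",
                name, len(idx), len(genes), max(min_set_size, 1),
            )
            continue
        members[name] = idx
    if not members:
        raise ValueError("no gene set passed the effective-size filter")

    rng = np.random.default_rng(seed)
    moments: dict[int, tuple[np.ndarray, np.ndarray, bool]] = {}
    all_enumerated = True
    for m in sorted({len(v) for v in members.values()}):
        moments[m] = _null_moments(z, m, n_permutations, rng, exact)
        all_enumerated &= moments[m][2]

    rows = {}
    for name, idx in members.items():
        observed = z[idx].mean(axis=0)
        null_mean, null_sd, _ = moments[len(idx)]
        zs = np.zeros_like(observed)
        np.divide(observed - null_mean, null_sd, out=zs, where=null_sd != 0)
        rows[name] = zs
    zmat = pd.DataFrame(rows, index=compendium.expression.columns).T
    zmat.index.name = "gene_set"
    return SleaMatrix(
        zscores=zmat,
        effective_size={k: len(v) for k, v in members.items()},
        n_permutations=0 if all_enumerated else n_permutations,
        seed=seed,
        dropped_sets=dropped,
    )


def superset_scores(slea: SleaMatrix, gene_sets: GeneSetCollection) -> SleaMatrix:
    """Aggregate member-set z-scores into the seven superset scores.

    The superset score per sample is the unweighted mean of its mapped
    member-set z-scores; supersets with no mapped (retained) set are omitted.
    """
    if not gene_sets.superset_map:
        raise ValueError("gene-set collection has no superset_map")
    rows = {}
    sizes = {}
    for label in SUPERSET_LABELS:
        mapped = [
            s for s, lab in gene_sets.superset_map.items()
            if lab == label and s in slea.zscores.index
        ]
        if not mapped:
            continue
        rows[label] = slea.zscores.loc[mapped].mean(axis=0).to_numpy()
        sizes[label] = len(mapped)
    if not rows:
        raise ValueError("no superset has a mapped gene set present in the SLEA matrix")
    zmat = pd.DataFrame(rows, index=slea.zscores.columns).T
    zmat.index.name = "superset"
    return SleaMatrix(
        zscores=zmat,
        effective_size=sizes,
        n_permutations=slea.n_permutations,
        seed=slea.seed,
        dropped_sets=slea.dropped_sets,
    )
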