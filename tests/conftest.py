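"""Shared fixtures: programmatic construction of small compendia."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from vaxendo.compendium import Compendium, GeneSetCollection


def make_compendium(
    values,
    genes=None,
    samples=None,
    days=None,
    studies=None,
    participants=None,
    platforms=None,
    sample_types=None,
    vaccines=None,
    gene_sets=None,
) -> Compendium:
    """Build a validated Compendium from a 2-D array plus optional metadata."""
    values = np.asarray(values, dtype=float)
    n_genes, n_samples = values.shape
    genes = genes or [f"g{i}" for i in range(n_genes)]
    samples = samples or [f"s{i}" for i in range(n_samples)]
    meta = pd.DataFrame(
        {
            "participant_id": participants or [f"p{i}" for i in range(n_samples)],
            "study_id": studies or ["study1"] * n_samples,
            "platform": platforms or ["platformA"] * n_samples,
            "sample_type": sample_types or ["whole_blood"] * n_samples,
            "vaccine": vaccines or ["vax1"] * n_samples,
            "day": days if days is not None else [0] * n_samples,
        },
        index=pd.Index(samples, name="sample_id"),
    )
    expr = pd.DataFrame(values, index=pd.Index(genes, name="gene"), columns=samples)
    return Compendium(expression=expr, samples=meta, gene_sets=gene_sets)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_compendium(rng):
    """50 genes x 12 samples across two studies, day 0."""
    return make_compendium(
        rng.normal(8, 1, (50, 12)),
        studies=["study1"] * 6 + ["study2"] * 6,
        platforms=["platformA"] * 6 + ["platformB"] * 6,
        sample_types=["whole_blood"] * 6 + ["pbmc"] * 6,
    )


@pytest.fixture
def gene_sets_small():
    return GeneSetCollection(
        sets={"setA": ["g0", "g1", "g2", "g3", "g4"], "setB": ["g5", "g6", "g7", "g8", "g9"]},
        superset_map={"setA": "inflammation", "setB": "T_cells"},
    )
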