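"""End-to-end orchestration of the analysis from a single config.

Stage order mirrors the analysis: normalization -> batch correction -> PVCA
-> SLEA -> endotypes -> antibody response -> classifier -> metascore ->
kinetics. Every stochastic stage takes an explicit seed from the config; a
manifest records input hashes, parameters and output hashes so a rerun with
an identical config is verifiably identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import asdict, dataclass, field

import pandas as pd
import yaml

from vaxendo import __version__
from vaxendo.compendium import (
    Compendium,
    load_compendium,
    read_gmt,
    read_superset_map,
)
from vaxendo.endotype import INFLAMMATORY_SETS, gap_statistic, hierarchical_clusters, label_endotypes
from vaxendo.etiology import BACTERIAL_GENES, VIRAL_GENES, bacterial_viral_score
from vaxendo.kinetics import compare_endotypes, compute_deltas, summarize_kinetics
from vaxendo.predict import select_features, train_evaluate
from vaxendo.preprocess import apply_batch_correction, fit_batch_model, quantile_normalize_within_study
from vaxendo.pvca import pvca
from vaxendo.response import compute_mfc, discretize_responders, load_titers, scale_mfc
from vaxendo.slea import SleaMatrix, slea_zscores, superset_scores

logger = logging.getLogger(__name__)

_KNOWN_KEYS = {
    "expr", "meta", "gmt", "supersets", "titers", "out_dir",
    "seed_slea", "seed_pvca", "seed_gap", "seed_classifier",
    "n_permutations", "min_set_size", "pvca_factors", "pvca_bootstrap",
    "cumvar_threshold", "k_max", "n_ref", "n_features", "n_folds",
    "importance_threshold", "inflammatory_sets",
}
_REQUIRED_SEEDS = ("seed_slea", "seed_pvca", "seed_gap", "seed_classifier")


@dataclass
class RunConfig:
    """Validated configuration of a full pipeline run."""

    expr: str
    meta: str
    gmt: str
    titers: str
    out_dir: str
    seed_slea: int
    seed_pvca: int
    seed_gap: int
    seed_classifier: int
    supersets: str | None = None
    n_permutations: int = 1000
    min_set_size: int = 5
    pvca_factors: list[str] = field(default_factory=lambda: ["study_id", "platform", "sample_type", "day"])
    pvca_bootstrap: int = 50
    cumvar_threshold: float = 0.60
    k_max: int = 6
    n_ref: int = 50
    n_features: int = 500
    n_folds: int = 10
    importance_threshold: float = 50.0
    #: Gene sets whose mean SLEA z defines the inflammatory score; defaults
    #: to the four MSigDB hallmark inflammatory sets.
    inflammatory_sets: list[str] = field(default_factory=lambda: list(INFLAMMATORY_SETS))

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - _KNOWN_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        missing = [k for k in _REQUIRED_SEEDS if k not in raw]
        if missing:
            raise ValueError(f"config missing explicit seeds: {missing}")
        return cls(**raw)


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_tsv(df: pd.DataFrame, path: str, **kwargs) -> str:
    df.to_csv(path, sep="\t", float_format="%.10g", **kwargs)
    return path


def run_all(config: RunConfig) -> dict:
    """Execute every stage in dependency order; return the run manifest.

    Any stage error halts the run with the stage name in the exception
    message. Outputs land in ``config.out_dir``; the manifest (also written
    as ``manifest.json``) records parameters, seeds and sha256 hashes of all
    inputs and outputs.
    """
    os.makedirs(config.out_dir, exist_ok=True)
    outputs: dict[str, str] = {}
    stages: list[str] = []

    def _stage(name: str):
        stages.append(name)
        logger.info("stage %s", name)

    try:
        _stage("load")
        gene_sets = read_gmt(config.gmt)
        if config.supersets:
            gene_sets.superset_map = read_superset_map(config.supersets)
        compendium = load_compendium(config.expr, config.meta, gene_sets)
        logger.info("loaded %d genes x %d samples", compendium.n_genes, compendium.n_samples)

        _stage("normalize")
        compendium = quantile_normalize_within_study(compendium)

        _stage("batch_correction")
        model = fit_batch_model(compendium)
        corrected = apply_batch_correction(compendium, model)
        outputs["corrected_expression"] = _write_tsv(
            corrected.expression, os.path.join(config.out_dir, "corrected_expression.tsv"),
            index_label="gene",
        )
        outputs["batch_model"] = _write_tsv(
            model.coefficients, os.path.join(config.out_dir, "batch_model.tsv"),
            index_label="gene",
        )
        with open(os.path.join(config.out_dir, "batch_aliasing.json"), "w") as fh:
            json.dump(
                {
                    "aliased": [list(c) for c in model.aliased],
                    "reference_levels": model.reference_levels,
                    "omitted_factors": model.omitted_factors,
                },
                fh, indent=2,
            )
        outputs["batch_aliasing"] = os.path.join(config.out_dir, "batch_aliasing.json")

        _stage("pvca")
        pvca_res = pvca(
            corrected,
            factors=config.pvca_factors,
            cumvar_threshold=config.cumvar_threshold,
            n_bootstrap=config.pvca_bootstrap,
            seed=config.seed_pvca,
        )
        outputs["pvca"] = _write_tsv(
            pvca_res.to_frame(), os.path.join(config.out_dir, "pvca.tsv"), index=False
        )

        _stage("slea")
        slea = slea_zscores(
            corrected, gene_sets,
            n_permutations=config.n_permutations,
            seed=config.seed_slea,
            min_set_size=config.min_set_size,
        )
        outputs["slea"] = _write_tsv(slea.zscores, os.path.join(config.out_dir, "slea.tsv"))
        supersets = superset_scores(slea, gene_sets) if gene_sets.superset_map else None
        if supersets is not None:
            outputs["slea_supersets"] = _write_tsv(
                supersets.zscores, os.path.join(config.out_dir, "slea_supersets.tsv")
            )

        _stage("endotype")
        pre_ids = corrected.samples.index[corrected.prevaccination_mask()]
        pre_slea = SleaMatrix(
            zscores=slea.zscores[pre_ids],
            effective_size=slea.effective_size,
            n_permutations=slea.n_permutations,
            seed=slea.seed,
            dropped_sets=slea.dropped_sets,
        )
        gap = gap_statistic(pre_slea, k_max=config.k_max, n_ref=config.n_ref, seed=config.seed_gap)
        clusters = hierarchical_clusters(pre_slea, k=3)
        assignment = label_endotypes(
            clusters, pre_slea, inflammatory_sets=tuple(config.inflammatory_sets), gap=gap
        )
        outputs["endotypes"] = _write_tsv(
            assignment.assignments, os.path.join(config.out_dir, "endotypes.tsv"),
            index_label="sample_id",
        )
        gap_df = pd.DataFrame(
            {"k": gap.ks, "gap": gap.gap, "se": gap.se, "log_wk": gap.log_wk}
        )
        gap_df["chosen_k"] = gap.chosen_k
        outputs["gap_curve"] = _write_tsv(
            gap_df, os.path.join(config.out_dir, "gap_curve.tsv"), index=False
        )

        _stage("response")
        titers = load_titers(config.titers)
        responses = discretize_responders(scale_mfc(compute_mfc(titers)))
        outputs["responses"] = _write_tsv(
            responses, os.path.join(config.out_dir, "responses.tsv"), index_label="participant_id"
        )

        _stage("classifier")
        features = select_features(corrected, responses, n=config.n_features)
        report = train_evaluate(
            corrected, responses, features, n_folds=config.n_folds, seed=config.seed_classifier
        )
        scaled = report.importances / report.importances.max() * 100.0
        report_json = {
            "metrics": report.metrics,
            "auroc_ci": list(report.auroc_ci),
            "per_vaccine_auroc": report.per_vaccine_auroc,
            "best_mtry": report.best_mtry,
            "tuning_trace": {str(k): v for k, v in report.tuning_trace.items()},
            "n_folds": report.n_folds,
            "seed": report.seed,
            "stratification": report.stratification,
            "top_genes_over_threshold": scaled[scaled > config.importance_threshold].index.tolist(),
            "oof_proba": report.oof_proba.round(6).to_dict(),
        }
        path = os.path.join(config.out_dir, "classifier_report.json")
        with open(path, "w") as fh:
            json.dump(report_json, fh, indent=2, sort_keys=True)
        outputs["classifier_report"] = path

        _stage("metascore")
        marker_genes = set(BACTERIAL_GENES + VIRAL_GENES)
        if marker_genes <= set(corrected.expression.index):
            meta_res = bacterial_viral_score(corrected)
            outputs["metascore"] = _write_tsv(
                meta_res.to_frame(), os.path.join(config.out_dir, "metascore.tsv"),
                index_label="sample_id",
            )
        else:
            missing = sorted(marker_genes - set(corrected.expression.index))
            logger.warning("metascore skipped: marker genes absent: %s", missing)

        _stage("kinetics")
        if supersets is not None:
            consensus = assignment.participant_consensus(corrected.samples)
            deltas = compute_deltas(supersets, corrected.samples, consensus)
            outputs["kinetics"] = _write_tsv(
                summarize_kinetics(deltas), os.path.join(config.out_dir, "kinetics.tsv"),
                index=False,
            )
            comparisons = compare_endotypes(deltas)
            outputs["kinetics_comparisons"] = _write_tsv(
                comparisons, os.path.join(config.out_dir, "kinetics_comparisons.tsv"),
                index=False,
            )
        else:
            logger.warning("kinetics skipped: no superset map supplied")
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stages[-1]!r}: {exc}") from exc

    manifest = {
        "version": __version__,
        "stages": stages,
        "config": asdict(config),
        "input_hashes": {
            k: _sha256(getattr(config, k))
            for k in ("expr", "meta", "gmt", "titers")
        },
        "output_hashes": {k: _sha256(p) for k, p in outputs.items()},
        "outputs": outputs,
    }
    path = os.path.join(config.out_dir, "manifest.json")
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
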