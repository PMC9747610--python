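"""Synthetic multi-study vaccine-transcriptomics compendia with planted structure.

The generator emulates the statistical structure the analysis assumes: an
additive Gaussian model on the log2 scale with participant endotypes shifting
gene modules, per-study / per-platform / per-sample-type batch effects,
post-vaccination kinetic responses (attenuated in the high-inflammatory
endotype), and multi-strain antibody titers whose day-28 boost depends on the
endotype. Ground-truth labels are returned for recovery tests.

Expression model, per gene g and sample s of participant i at day d:

    y(g, s) = baseline(g)
            + endotype_shift(g, endotype(i))
            + kinetic(g, d, endotype(i))
            + batch(study(s), g) + platform(platform(s), g) + sampletype(type(s), g)
            + N(0, noise_sd)

The high-inflammatory endotype (inflam.hi) raises the inflammation, ISG and
monocyte/DC modules by +delta; the low endotype (inflam.lo) raises the T/NK/B
cell and E2F/MYC modules by +delta; the middle endotype applies +delta/2 to
both groups.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from vaxendo.compendium import Compendium, GeneSetCollection, SUPERSET_LABELS

#: Supersets elevated in the inflam.hi endotype.
HI_SUPERSETS = ("inflammation", "ISGs", "monocytes_DCs")
#: Supersets elevated in the inflam.lo endotype.
LO_SUPERSETS = ("T_cells", "NK_cells", "B_cells", "E2F_MYC")

ENDOTYPES = ("inflam.lo", "inflam.mid", "inflam.hi")
#: Endotype score entering the titer model (lo/mid/hi).
ENDOTYPE_SCORE = {"inflam.lo": 0.0, "inflam.mid": 0.5, "inflam.hi": 1.0}

# named sub-streams of the master seed, so e.g. adding strains never
# perturbs the expression draws
_STREAMS = {
    "baseline": 0,
    "assignment": 1,
    "batch": 2,
    "platform": 3,
    "sampletype": 4,
    "noise": 5,
    "titer": 6,
}


def _default_module_sizes() -> dict[str, int]:
    return {label: 50 for label in SUPERSET_LABELS}


def _default_kinetics() -> dict[str, dict[int, float]]:
    # day-1/3 innate induction, day-7 plasmablast/B-cell induction: the
    # canonical shape of blood transcriptomic vaccine responses
    return {
        "inflammation": {1: 1.0, 3: 0.5},
        "monocytes_DCs": {1: 0.8, 3: 0.4},
        "ISGs": {1: 1.0, 3: 0.3},
        "B_cells": {7: 0.6, 14: 0.3},
    }


@dataclass
class SimConfig:
    """Configuration of the synthetic compendium.

    Effect sizes are in log2 expression units. ``kinetic_effects`` maps
    superset -> day -> mean induction; for inflam.hi participants the
    induction of the inflammatory supersets (inflammation, ISGs,
    monocytes/DCs) is multiplied by ``kinetic_attenuation_hi``.
    """

    n_studies: int = 3
    participants_per_study: int = 30
    n_genes: int = 1000
    module_sizes: dict[str, int] = field(default_factory=_default_module_sizes)
    endotype_proportions: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)
    endotype_effect_delta: float = 1.0
    batch_sd: float = 0.5
    platform_sd: float = 0.0
    sampletype_sd: float = 0.0
    noise_sd: float = 0.25
    timepoints: tuple[int, ...] = (0,)
    kinetic_effects: dict[str, dict[int, float]] = field(default_factory=_default_kinetics)
    kinetic_attenuation_hi: float = 0.5
    titer_beta: float = 1.5
    n_strains: int = 3
    titer_noise_sd: float = 1.0
    titer_baseline_log2_mean: float = 5.0
    titer_baseline_log2_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.endotype_proportions) - 1.0) > 1e-12:
            raise ValueError("endotype_proportions must sum to 1")
        for name in ("batch_sd", "platform_sd", "sampletype_sd", "noise_sd", "titer_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if 0 not in self.timepoints:
            raise ValueError("timepoints must include day 0")
        unknown = set(self.module_sizes) - set(SUPERSET_LABELS)
        if unknown:
            raise ValueError(f"unknown module labels: {sorted(unknown)}")
        if sum(self.module_sizes.values()) > self.n_genes:
            raise ValueError("module sizes exceed n_genes")
        if self.n_strains < 1:
            raise ValueError("n_strains must be >= 1")

    def rng(self, stream: str) -> np.random.Generator:
        """Independent generator for a named logical component."""
        return np.random.default_rng(
            np.random.SeedSequence(entropy=self.seed, spawn_key=(_STREAMS[stream],))
        )


@dataclass
class GroundTruth:
    """Planted labels and analytic variance structure of a simulated compendium.

    ``endotype`` is one label per participant, constant across that
    participant's samples. ``variance_fractions`` are the analytic day-0
    per-gene variance shares (averaged over genes) attributable to each
    planted factor; ``responder_propensity`` is the endotype score scaled by
    ``titer_beta`` (the planted mean log2-MFC).
    """

    endotype: pd.Series
    variance_fractions: dict[str, float]
    responder_propensity: pd.Series


#: Bacterial/viral metascore marker symbols, planted (signal-free) among the
#: background genes when room allows, so the etiology stage runs end-to-end.
_METASCORE_GENES = ("HK3", "TNIP1", "GPAA1", "CTSB", "IFI27", "JUP", "LAX1")


def _gene_module_layout(config: SimConfig) -> tuple[list[str], GeneSetCollection, dict[str, np.ndarray]]:
    genes = [f"G{i:05d}" for i in range(config.n_genes)]
    n_module = sum(config.module_sizes.get(lbl, 0) for lbl in SUPERSET_LABELS)
    n_background = config.n_genes - n_module
    if n_background >= len(_METASCORE_GENES):
        for j, symbol in enumerate(_METASCORE_GENES):
            genes[n_module + j] = symbol
    sets: dict[str, list[str]] = {}
    superset_map: dict[str, str] = {}
    masks: dict[str, np.ndarray] = {}
    cursor = 0
    for label in SUPERSET_LABELS:
        size = config.module_sizes.get(label, 0)
        if size == 0:
            continue
        members = genes[cursor : cursor + size]
        cursor += size
        set_name = f"mod_{label}"
        sets[set_name] = members
        superset_map[set_name] = label
        mask = np.zeros(config.n_genes, dtype=bool)
        mask[cursor - size : cursor] = True
        masks[label] = mask
    return genes, GeneSetCollection(sets=sets, superset_map=superset_map), masks


def _endotype_shift_matrix(config: SimConfig, masks: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
    """Per-endotype additive shift vector over genes."""
    hi_mask = np.zeros(config.n_genes, dtype=bool)
    lo_mask = np.zeros(config.n_genes, dtype=bool)
    for label in HI_SUPERSETS:
        if label in masks:
            hi_mask |= masks[label]
    for label in LO_SUPERSETS:
        if label in masks:
            lo_mask |= masks[label]
    delta = config.endotype_effect_delta
    return {
        "inflam.hi": np.where(hi_mask, delta, 0.0),
        "inflam.lo": np.where(lo_mask, delta, 0.0),
        "inflam.mid": np.where(hi_mask | lo_mask, delta / 2.0, 0.0),
    }


def _planted_variance_fractions(
    config: SimConfig, shifts: dict[str, np.ndarray]
) -> dict[str, float]:
    p = np.asarray(config.endotype_proportions, dtype=float)
    shift_mat = np.stack([shifts[e] for e in ENDOTYPES])  # 3 x genes
    mean_shift = p @ shift_mat
    endo_var = p @ (shift_mat**2) - mean_shift**2
    # identifiable (centered) variance of a factor with a iid level effects is
    # sigma^2 (a-1)/a: the grand mean across levels is absorbed in the baseline
    n_platforms = min(2, config.n_studies)
    n_sampletypes = min(2, config.n_studies)
    components = {
        "study": np.full(
            config.n_genes,
            config.batch_sd**2 * (config.n_studies - 1) / config.n_studies,
        ),
        "platform": np.full(
            config.n_genes,
            config.platform_sd**2 * (n_platforms - 1) / max(n_platforms, 1),
        ),
        "sample_type": np.full(
            config.n_genes,
            config.sampletype_sd**2 * (n_sampletypes - 1) / max(n_sampletypes, 1),
        ),
        "endotype": endo_var,
        "resid": np.full(config.n_genes, config.noise_sd**2),
    }
    total = sum(components.values())
    total = np.where(total == 0, 1.0, total)
    return {name: float(np.mean(comp / total)) for name, comp in components.items()}


def simulate_compendium(
    config: SimConfig,
) -> tuple[Compendium, GeneSetCollection, GroundTruth]:
    """Generate a compendium, its planted gene modules and the ground truth.

    Deterministic for a fixed ``config.seed``. Each study carries exactly one
    platform and one sample type (platforms/types alternate across studies),
    reproducing the confounding of real multi-study resources.
    """
    genes, collection, masks = _gene_module_layout(config)
    shifts = _endotype_shift_matrix(config, masks)

    baseline = config.rng("baseline").normal(8.0, 1.0, size=config.n_genes)

    studies = [f"study{i + 1}" for i in range(config.n_studies)]
    platforms = {s: f"platform{i % 2 + 1}" for i, s in enumerate(studies)}
    sample_types = {s: ("whole_blood" if i % 2 == 0 else "pbmc") for i, s in enumerate(studies)}
    vaccines = {s: f"vaccine{i % 2 + 1}" for i, s in enumerate(studies)}

    rng_batch = config.rng("batch")
    batch_eff = {s: rng_batch.normal(0.0, config.batch_sd, config.n_genes) for s in studies}
    rng_plat = config.rng("platform")
    plat_eff = {
        p: rng_plat.normal(0.0, config.platform_sd, config.n_genes)
        for p in sorted(set(platforms.values()))
    }
    rng_st = config.rng("sampletype")
    st_eff = {
        t: rng_st.normal(0.0, config.sampletype_sd, config.n_genes)
        for t in sorted(set(sample_types.values()))
    }

    rng_assign = config.rng("assignment")
    participants: list[str] = []
    part_study: dict[str, str] = {}
    for s in studies:
        for j in range(config.participants_per_study):
            pid = f"{s}_P{j + 1:03d}"
            participants.append(pid)
            part_study[pid] = s
    endotype = pd.Series(
        rng_assign.choice(ENDOTYPES, size=len(participants), p=config.endotype_proportions),
        index=pd.Index(participants, name="participant_id"),
        name="endotype",
    )

    days = sorted(config.timepoints)
    rng_noise = config.rng("noise")
    columns: list[str] = []
    meta_rows: list[dict] = []
    data = np.empty((config.n_genes, len(participants) * len(days)))
    attenuated = set(HI_SUPERSETS)
    col = 0
    for pid in participants:
        study = part_study[pid]
        endo = endotype[pid]
        base = (
            baseline
            + shifts[endo]
            + batch_eff[study]
            + plat_eff[platforms[study]]
            + st_eff[sample_types[study]]
        )
        for day in days:
            kin = np.zeros(config.n_genes)
            for label, per_day in config.kinetic_effects.items():
                if label not in masks or day not in per_day:
                    continue
                amount = per_day[day]
                if endo == "inflam.hi" and label in attenuated:
                    amount *= config.kinetic_attenuation_hi
                kin[masks[label]] += amount
            noise = rng_noise.normal(0.0, config.noise_sd, config.n_genes)
            sid = f"{pid}_d{day}"
            data[:, col] = base + kin + noise
            columns.append(sid)
            meta_rows.append(
                {
                    "sample_id": sid,
                    "participant_id": pid,
                    "study_id": study,
                    "platform": platforms[study],
                    "sample_type": sample_types[study],
                    "vaccine": vaccines[study],
                    "day": day,
                    "age_years": np.nan,
                    "sex": "NA",
                    "ethnicity": "NA",
                }
            )
            col += 1

    expression = pd.DataFrame(data, index=pd.Index(genes, name="gene"), columns=columns)
    samples = pd.DataFrame(meta_rows).set_index("sample_id")
    compendium = Compendium(expression=expression, samples=samples, gene_sets=collection)
    truth = GroundTruth(
        endotype=endotype,
        variance_fractions=_planted_variance_fractions(config, shifts),
        responder_propensity=endotype.map(ENDOTYPE_SCORE).astype(float) * config.titer_beta,
    )
    return compendium, collection, truth


def simulate_titers(truth: GroundTruth, config: SimConfig) -> pd.DataFrame:
    """Generate a multi-strain titer table for the participants in ``truth``.

    Per participant and strain the day-0 titer is log-normal; the day-28 log2
    titer adds ``max(0, titer_beta * endotype_score + N(0, titer_noise_sd))``,
    a non-negative boost whose mean tracks the endotype. Deterministic for a
    fixed ``config.seed``.
    """
    if truth.endotype.empty:
        raise ValueError("ground truth has no participants")
    rng = config.rng("titer")
    rows: list[dict] = []
    for pid, endo in truth.endotype.items():
        study = pid.rsplit("_P", 1)[0]
        study_idx = int(study.replace("study", "")) - 1 if study.startswith("study") else 0
        vaccine = f"vaccine{study_idx % 2 + 1}"
        score = ENDOTYPE_SCORE[endo]
        for k in range(config.n_strains):
            strain = f"strain{k + 1}"
            log2_day0 = rng.normal(config.titer_baseline_log2_mean, config.titer_baseline_log2_sd)
            boost = max(0.0, config.titer_beta * score + rng.normal(0.0, config.titer_noise_sd))
            for day, log2_titer in ((0, log2_day0), (28, log2_day0 + boost)):
                rows.append(
                    {
                        "participant_id": pid,
                        "study_id": study,
                        "vaccine": vaccine,
                        "strain": strain,
                        "day": day,
                        "titer": float(2.0**log2_titer),
                        "assay": "HAI",
                    }
                )
    return pd.DataFrame(rows)
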