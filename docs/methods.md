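# Methods

This note documents the statistical procedures implemented in `vaxendo`,
the assumptions behind them, the defaults that matter, and what the
synthetic-data generator does and does not emulate.

## Data model

A compendium is a log2 expression matrix (gene symbols × sample ids), a
sample-metadata table (participant, study, platform, whole-blood/PBMC sample
type, vaccine, day relative to vaccination, optional age/sex/ethnicity) and
an optional gene-set collection (GMT). Days −7 and 0 are pre-vaccination
throughout. Gene symbols are matched case-sensitively with no alias
resolution; expression must be finite after loading (the loader either
rejects missing cells — the default — or imputes per-gene medians). TSV
files are tab-separated UTF-8 with `NA`/empty as the only missing tokens.

## Synthetic-data generator

The generator emulates a multi-study compendium as an additive Gaussian
model on the log2 scale:

    y(g, s) = baseline(g) + endotype_shift(g, e) + kinetic(g, day, e)
            + batch(study, g) + platform_effect + sampletype_effect + ε

Seven gene modules mirror the cell-subset/pathway supersets (T cells, NK
cells, B cells, monocytes/DCs, inflammation, E2F/MYC, ISGs; 50 genes each by
default out of 1000). The high-inflammatory endotype raises the
inflammation/ISG/monocyte-DC modules by `delta`, the low endotype raises the
T/NK/B/E2F-MYC modules by `delta`, and the middle endotype applies `delta/2`
to both groups — so endotype means are collinear, as the "mixed profile" of
the middle group suggests. Each participant keeps one endotype across all
samples. Each study carries exactly one platform and one sample type,
reproducing the confounding of real multi-study resources and making
rank-deficiency handling in the batch model testable. Post-vaccination
kinetics add per-module, per-day inductions (defaults: innate modules at
days 1/3, B cells at days 7/14), multiplied by an attenuation factor
(default 0.5) on the innate modules for high-inflammatory participants.
Titers are log-normal at day 0 with a non-negative day-28 log2 boost
`max(0, titer_beta · endotype_score + noise)`, `endotype_score ∈ {0, ½, 1}`
for lo/mid/hi. Defaults (`delta = 1`, `noise_sd = 0.25`, `batch_sd = 0.5`,
`titer_beta = 1.5`, `titer_noise_sd = 1`) are chosen so planted structure is
clearly present but not trivially separable at the per-gene level.

Named, independently seeded random streams (baseline, assignment, batch,
platform, sample type, noise, titer) derive from the master seed, so e.g.
adding strains never perturbs expression draws; identical seeds give
byte-identical outputs.

The generator's `GroundTruth.variance_fractions` report the *identifiable*
per-gene variance shares: for a factor with `a` realized levels the centered
variance is `σ²(a−1)/a`, because the grand mean across levels is absorbed in
the baseline and cannot be attributed by any decomposition of the data.

What the generator does **not** emulate: count-level (negative-binomial)
noise, probe effects, gene–gene correlation beyond the planted modules,
titer censoring/detection limits, and endotype–study association (endotypes
are assigned independently of study). Recovery results on this generator
therefore show correctness of the machinery under the model's assumptions,
not performance on real data.

## Quantile normalization and batch correction

Within each study, every sample's sorted values are replaced by the
across-sample mean of order statistics; tied input values receive the mean
of the normalized values at their tied ranks; single-sample studies are
left unchanged.

Batch effects are estimated by per-gene OLS of expression on categorical
study, sample type and platform, using pre-vaccination samples only, and the
estimated factor offsets are subtracted from all samples (the intercept is
retained). When the design is rank-deficient — platform or sample type
nested in study, as in the generator — candidate columns are scanned in the
order study → sample type → platform and aliased columns dropped greedily,
so the finer factor (study) absorbs confounded variance; dropped columns and
reference levels are recorded on the model. Single-level factors are omitted
with a log entry; unseen factor levels at application time are an error.

A consequence worth knowing: when endotype composition differs between
studies, the per-study means removed by the correction contain a bit of
endotype signal, displacing each study's samples slightly along the endotype
contrast. With few studies and strong endotypes this plants visible
within-endotype substructure in downstream clustering. This is a property of
mean-subtraction batch correction itself, not of the implementation, and it
motivates assessing cluster-number selection on single-study data (below).

## PVCA

Gene-standardized expression defines a sample–sample covariance; its leading
principal components (smallest set reaching the cumulative-variance
threshold, default 0.60) are each decomposed into variance components for
all requested factors jointly plus a residual. The estimator is a
Haseman–Elston-style method of moments: the products of centered PC scores
are regressed on same-level indicator matrices. Two details matter:

- Gene standardization centers every gene, so PC score vectors are
  orthogonal to the all-ones vector; the moment design therefore uses the
  centered indicators `M S_f M` (`M = I − 11'/n`). Without this the
  same-level products are attenuated and factors are under-attributed.
- Components are truncated at zero, normalized per PC and averaged with
  eigenvalue weights.

Uncertainty comes from resampling participants (all their samples together)
with replacement; percentile 2.5/97.5 intervals are reported. Bootstrap
copies of one sample share their noise draw, so products between copies of
the same original sample are excluded from the moment regression — otherwise
duplicate pairs read as factor covariance and null factors get inflated
intervals.

Factor encoding: age in 10-year bins ("20-29", …), day kept distinct up to
20 and collapsed to one "≥20" category above (a declared reading of
left-censoring at 20 days, recorded in the result object), missing values as
an explicit level. A factor with as many levels as samples is rejected as
unidentifiable.

The default 0.60 threshold follows the common PVCA screening convention and
is reported in the result. For *recovering the full variance decomposition*
(as in the planted-fraction checks) the threshold is set to 1.0: truncating
the spectrum discards mostly-residual components and mechanically
under-counts the residual share, a bias of the truncation rule rather than
of the estimator.

Tests and the acceptance script use 50–200 bootstrap replicates to stay
fast; 4,000 is the production default on the CLI.

## SLEA

Expression is gene-standardized (per gene across all samples), then each
set's observed per-sample mean is compared to the means of random equal-size
gene sets: `z(S, s) = (obs − μ_null(s)) / σ_null(s)`, with a zero null sd
defining z = 0. One shared block of permutations per set size makes
equal-size sets face an identical null and reduces cost to O(P·G); when the
number of distinct subsets is small (or `exact=True`) the null is fully
enumerated, and enumeration agrees with the closed-form finite-population
null (mean = column mean; variance = column variance/m · (G−m)/(G−1)).
Null standard deviations use the population convention (ddof = 0), which is
exact under enumeration. Sets with fewer than 5 matched genes are dropped
(configurable) and logged. Default 1000 permutations; a seed is required.
Superset scores are unweighted means of member-set z-scores.

Standardizing before scoring is a declared convention (it makes nulls
comparable across sets); scoring is strictly within-sample given the scored
matrix, which the suite verifies with standardization disabled.

## Endotypes

Clustering uses Euclidean distance and complete linkage on SLEA column
vectors of pre-vaccination samples; the dendrogram is cut at k clusters.
The Gap statistic uses within-cluster pairwise squared-distance dispersion
`W_k = Σ_r D_r/(2 n_r)`, reference datasets uniform over the per-feature
range (chosen over the PCA-rotated box for determinism and simplicity),
`se(k) = sd_ref(log W_k)·√(1+1/B)`, and the one-standard-error rule
(smallest k with `Gap(k) ≥ Gap(k+1) − se(k+1)`); identical points give k = 1
with a warning. Labeling requires k = 3: clusters are ranked by the mean
z-score of the four hallmark inflammatory sets and named
`inflam.lo/mid/hi`; labels depend only on scores, never on cluster ids.
Tertile annotations use type-7 quantiles at 1/3 and 2/3 with ties assigned
to the lower bin. A participant-level consensus (majority label, ties broken
by the participant's mean inflammatory score) is provided for kinetics.

Temporal stability is a one-way random-effects variance ratio: per gene set,
between-participant variance over total variance across each participant's
eligible samples (day −7/0 and day ≥ 70), truncated to [0, 1], aggregated as
the mean over sets. This variance-ratio definition is a declared stand-in
for trait-stability metrics defined elsewhere; it is 1 when participants
are internally constant but different from each other, and ≈ 0 for i.i.d.
scores.

## Antibody response

Per strain, fold change = titer at the in-window day nearest 28 (±2 days;
ties toward the later day) over the day-0 titer (day −7 fallback); MFC is
the maximum over strains; participants lacking a qualifying strain are
omitted with a log entry. Scaled MFC is the within-vaccine z-score of log2
MFC (sample sd); single-participant vaccines get a missing value and a
zero-variance vaccine scales to 0, both logged. Responder calls are per
study: high iff MFC ≥ 70th percentile, low iff MFC ≤ 30th percentile
(type-7 quantiles), otherwise moderate; when the two thresholds coincide
(all-equal MFCs) everyone is moderate — there is no information to rank.
Studies under 3 participants are all moderate with a warning. Because the
percentile rule is invariant under monotone transforms, raw-ratio and log2
MFC give identical labels.

## Response classifier

Features are the top-500 genes by variance across pre-vaccination samples of
participants with response data (ties broken lexicographically). Each
participant's pre-vaccination samples are averaged into one feature vector,
so cross-validation folds split participants and repeated samples cannot
leak across folds. Moderate responders are excluded. The per-split feature
count is tuned over {√p, p/10, p/3} (500 trees) by stratified tenfold CV
maximizing pooled out-of-fold auROC; the winning configuration's pooled
out-of-fold predictions are the reported assessment and a final all-data
forest provides impurity importances, scaled so the maximum is 100%.
Stratification is by class only (recorded in the report). Reported metrics:
auROC with a Hanley–McNeil CI, accuracy/PPV/NPV/sensitivity/specificity at
the 0.5 threshold, Brier score, and per-vaccine out-of-fold auROC.
Everything is deterministic for a fixed seed in single-threaded mode.

Significance uses label permutation against the fixed out-of-fold scores:
`p = (1 + #{perm auROC ≥ observed}) / (n_perm + 1)`, which is valid and
slightly conservative. Signature scoring is mean log2 expression of present
up-genes minus present down-genes (arithmetic means on the log scale, i.e.
geometric means of intensities), with the same permutation test.

## Etiology metascore

`score = mean(HK3, TNIP1, GPAA1, CTSB) − mean(IFI27, JUP, LAX1)` on
batch-corrected log2 expression; `score ≥ 0` ⇒ bacterial-like. All seven
genes are required — the published weights assume the full marker set, so
there is no partial scoring. The generator plants these symbols among its
background (signal-free) genes so the stage runs end to end on synthetic
data.

## Kinetics

Per participant, superset and day bin (defaults 1, 3, 7, 14 with ±1/±1/±2/±2
tolerance and an open 21+ bin), delta = post score − pre score (day 0
preferred, −7 fallback; multiple in-bin samples resolve to the day nearest
the bin center, ties later). Endotype pairs are compared by two-sided
Wilcoxon rank-sum on participant deltas — exact for combined n ≤ 25 without
ties, full enumeration with ties up to n ≤ 12, otherwise the normal
approximation with continuity correction — with effect size the difference
of group medians (a declared convention) and BH correction across the whole
comparisons table.

## Statistical primitives

scipy/scikit-learn back the primitives (Fisher's exact with the
probability-mass two-sided convention, Mann–Whitney, Kruskal–Wallis,
Spearman, adjusted Rand index); auROC is the midrank Mann–Whitney form and
BH is implemented directly (step-up, monotone, capped at 1). Kruskal–Wallis
additionally enumerates the exact permutation null of the tie-corrected H
for combined n ≤ 10. The Kruskal–Wallis chi-square p with two groups equals
the Wilcoxon normal approximation *without* continuity correction; the suite
checks that identity with continuity disabled. All primitives are tested
against independent enumeration oracles regardless of backend.

## Pipeline

`run_all` executes load → quantile normalization → batch correction → PVCA
→ SLEA → endotype discovery → antibody response → classifier → metascore →
kinetics from one strictly-validated config (unknown keys rejected, every
stochastic stage seeded explicitly), logs per-stage counts so silent
filtering is impossible, and writes a manifest with input/output SHA-256
hashes; reruns with the same config are hash-identical. Any stage error
halts the run naming the stage.

## Problem sizes used in tests and the acceptance script

Endotype recovery: 90 participants, 1000 genes (7×50 module genes), 20
seeds, 300 SLEA permutations, 50 Gap references. The single-study design
isolates cluster-number selection from the batch-correction side effect
described above; batch correction is assessed separately. PVCA recovery: 210
genes, 120 samples over 4 studies, 50 bootstraps, full-spectrum threshold.
Classifier: 300 participants, 1000 genes, 500 features, tenfold CV;
permutation size over 200 null datasets of 40 samples × 30 genes at 199
permutations. These sizes were chosen as the smallest at which the planted
effects are estimable with comfortable margins.

## Known limitations

- The batch model is fixed-effects mean subtraction; no empirical-Bayes
  shrinkage (ComBat-style), so very small studies are corrected noisily.
- PVCA's method-of-moments estimator trades a little efficiency for
  determinism and robustness on null components; REML would be marginally
  more efficient on strongly structured components.
- The Gap statistic with a uniform-range reference over-splits strongly
  elongated clusters; with the per-sample SLEA scaling this matters when
  module dimensionality is very low.
- The classifier's tuning-then-assessment reuses the same cross-validation
  split (tuning optimism is not nested away); the permutation test guards
  the null calibration.
- Temporal stability is a variance ratio, not a reimplementation of any
  specific published trait-stability metric.
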