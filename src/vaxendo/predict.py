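"""High-vs-low responder classification from pre-vaccination expression.

A random forest is trained on the top-variance genes of pre-vaccination
samples, tuned (per-split feature count) and assessed by stratified tenfold
cross-validation pooled out-of-fold, reporting auROC, accuracy, PPV, NPV,
sensitivity, specificity and Brier score. Fixed gene signatures are scored
as mean(up) - mean(down) on the log2 scale, with label-permutation
significance for their auROC.

Features are participant-level: a participant's pre-vaccination samples are
averaged into one vector, so folds split participants and repeated samples
cannot leak across folds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold

from vaxendo.compendium import Compendium
from vaxendo.stats import auroc

logger = logging.getLogger(__name__)

N_FEATURES = 500
N_FOLDS = 10
N_TREES = 500


@dataclass
class Signature:
    """A fixed gene signature: up-regulated and (optionally) down-regulated genes."""

    name: str
    up_genes: list[str]
    down_genes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        overlap = set(self.up_genes) & set(self.down_genes)
        if overlap:
            raise ValueError(f"genes in both up and down lists: {sorted(overlap)}")
        if not (self.up_genes or self.down_genes):
            raise ValueError("signature must contain at least one gene")


@dataclass
class ClassifierReport:
    """Cross-validated random-forest evaluation.

    ``oof_proba`` holds pooled out-of-fold probabilities of the high class,
    one per participant; ``metrics`` the pooled performance numbers;
    ``importances`` the final-model impurity importances (raw); the tuning
    trace records the cross-validated auROC of every candidate per-split
    feature count.
    """

    oof_proba: pd.Series
    labels: pd.Series
    fold_of: pd.Series
    metrics: dict[str, float]
    auroc_ci: tuple[float, float]
    per_vaccine_auroc: dict[str, float]
    features: list[str]
    importances: pd.Series
    tuning_trace: dict[int, float]
    best_mtry: int
    n_folds: int
    seed: int
    stratification: str = "class only (not study/vaccine)"


def _qualifying_samples(compendium: Compendium, responses: pd.DataFrame) -> pd.DataFrame:
    """Pre-vaccination samples of participants with antibody-response data."""
    meta = compendium.samples
    mask = compendium.prevaccination_mask() & meta["participant_id"].isin(responses.index)
    return meta[mask]


def select_features(
    compendium: Compendium, responses: pd.DataFrame, n: int = N_FEATURES
) -> list[str]:
    """Top-n genes by variance across pre-vaccination samples with response data.

    Ties are broken by gene symbol (lexicographic), so the list is stable
    across runs. If fewer than n genes exist, all are returned with a warning.
    """
    qualifying = _qualifying_samples(compendium, responses)
    if qualifying.empty:
        raise ValueError("no pre-vaccination sample with response data")
    expr = compendium.expression[qualifying.index]
    variances = expr.var(axis=1, ddof=1)
    ranked = variances.to_frame("var").reset_index(names="gene")
    ranked = ranked.sort_values(["var", "gene"], ascending=[False, True], kind="stable")
    if len(ranked) < n:
        logger.warning("only %d genes available (< %d); returning all", len(ranked), n)
        return ranked["gene"].tolist()
    return ranked["gene"].head(n).tolist()


def _participant_matrix(
    compendium: Compendium, responses: pd.DataFrame, features: list[str]
) -> tuple[pd.DataFrame, pd.Series, pd.Series]:
    """One averaged pre-vaccination feature vector per high/low participant."""
    labeled = responses[responses["responder"].isin(["high", "low"])]
    qualifying = _qualifying_samples(compendium, labeled)
    if qualifying.empty:
        raise ValueError("no pre-vaccination sample for any high/low participant")
    expr = compendium.expression.loc[features, qualifying.index]
    X = expr.T.groupby(qualifying["participant_id"]).mean()
    y = labeled.loc[X.index, "responder"].eq("high").astype(int)
    vaccine = labeled.loc[X.index, "vaccine"]
    return X, y, vaccine


def _mtry_grid(p: int) -> list[int]:
    candidates = [int(np.sqrt(p)), p // 10, p // 3]
    grid = sorted({max(1, c) for c in candidates})
    return grid


def _hanley_mcneil_ci(a: float, n_pos: int, n_neg: int) -> tuple[float, float]:
    q1 = a / (2 - a)
    q2 = 2 * a**2 / (1 + a)
    var = (a * (1 - a) + (n_pos - 1) * (q1 - a**2) + (n_neg - 1) * (q2 - a**2)) / (n_pos * n_neg)
    half = norm.ppf(0.975) * np.sqrt(max(var, 0.0))
    return (float(max(0.0, a - half)), float(min(1.0, a + half)))


def train_evaluate(
    compendium: Compendium,
    responses: pd.DataFrame,
    features: list[str],
    n_folds: int = N_FOLDS,
    seed: int = 0,
    n_trees: int = N_TREES,
) -> ClassifierReport:
    """Tune and evaluate the random-forest responder classifier.

    The per-split feature count (mtry) is tuned over {sqrt(p), p/10, p/3} by
    stratified ``n_folds``-fold cross-validation maximizing pooled
    out-of-fold auROC; the winning configuration's pooled out-of-fold
    predictions are the reported assessment, and a final all-data forest
    provides feature importances. Moderate responders never enter.
    Deterministic for a fixed seed (single-threaded).
    """
    X, y, vaccine = _participant_matrix(compendium, responses, features)
    class_counts = y.value_counts()
    if len(class_counts) < 2:
        raise ValueError("both high and low responders are required")
    if class_counts.min() < n_folds:
        raise ValueError(
            f"minority class has {class_counts.min()} participants (< {n_folds} folds)"
        )

    ss = np.random.SeedSequence(seed)
    fold_seed, rf_seed = (int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(2))
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=fold_seed)
    folds = list(skf.split(X, y))

    Xv = X.to_numpy(dtype=float)
    yv = y.to_numpy()
    trace: dict[int, float] = {}
    oof_by_mtry: dict[int, np.ndarray] = {}
    for mtry in _mtry_grid(X.shape[1]):
        oof = np.full(len(y), np.nan)
        for train_idx, test_idx in folds:
            clf = RandomForestClassifier(
                n_estimators=n_trees,
                max_features=mtry,
                random_state=rf_seed,
                n_jobs=1,
            )
            clf.fit(Xv[train_idx], yv[train_idx])
            oof[test_idx] = clf.predict_proba(Xv[test_idx])[:, list(clf.classes_).index(1)]
        trace[mtry] = auroc(oof, yv)
        oof_by_mtry[mtry] = oof
    best_mtry = max(trace, key=lambda m: (trace[m], -m))
    oof = oof_by_mtry[best_mtry]

    pred = (oof >= 0.5).astype(int)
    tp = int(((pred == 1) & (yv == 1)).sum())
    tn = int(((pred == 0) & (yv == 0)).sum())
    fp = int(((pred == 1) & (yv == 0)).sum())
    fn = int(((pred == 0) & (yv == 1)).sum())
    a = auroc(oof, yv)
    metrics = {
        "auroc": a,
        "accuracy": (tp + tn) / len(yv),
        "ppv": tp / (tp + fp) if tp + fp else np.nan,
        "npv": tn / (tn + fn) if tn + fn else np.nan,
        "sensitivity": tp / (tp + fn) if tp + fn else np.nan,
        "specificity": tn / (tn + fp) if tn + fp else np.nan,
        "brier": float(np.mean((oof - yv) ** 2)),
    }

    per_vaccine = {}
    for vac, grp in vaccine.groupby(vaccine):
        sub = y.loc[grp.index]
        if sub.nunique() < 2:
            continue
        idx = [X.index.get_loc(i) for i in grp.index]
        per_vaccine[vac] = auroc(oof[idx], yv[idx])

    final = RandomForestClassifier(
        n_estimators=n_trees, max_features=best_mtry, random_state=rf_seed, n_jobs=1
    )
    final.fit(Xv, yv)

    fold_of = pd.Series(-1, index=X.index, dtype=int)
    for f, (_, test_idx) in enumerate(folds):
        fold_of.iloc[test_idx] = f

    return ClassifierReport(
        oof_proba=pd.Series(oof, index=X.index, name="p_high"),
        labels=y,
        fold_of=fold_of,
        metrics=metrics,
        auroc_ci=_hanley_mcneil_ci(a, int((yv == 1).sum()), int((yv == 0).sum())),
        per_vaccine_auroc=per_vaccine,
        features=list(X.columns),
        importances=pd.Series(final.feature_importances_, index=X.columns, name="importance"),
        tuning_trace=trace,
        best_mtry=best_mtry,
        n_folds=n_folds,
        seed=seed,
    )


def classifier_permutation_p(report: ClassifierReport, n_perm: int = 1000, seed: int = 0) -> float:
    """Label-permutation p-value of the pooled out-of-fold auROC.

    p = (1 + #{permuted auROC >= observed}) / (n_perm + 1).
    """
    rng = np.random.default_rng(seed)
    scores = report.oof_proba.to_numpy()
    labels = report.labels.to_numpy().copy()
    observed = report.metrics["auroc"]
    count = 0
    for _ in range(n_perm):
        rng.shuffle(labels)
        if auroc(scores, labels) >= observed:
            count += 1
    return (1 + count) / (n_perm + 1)


def scaled_importance(report: ClassifierReport, threshold_pct: float) -> list[str]:
    """Genes whose importance, scaled so the maximum is 100, strictly exceeds
    ``threshold_pct``. All-zero importances yield an empty list with a warning."""
    raw = report.importances
    if raw.max() == 0:
        logger.warning("all importances are zero; empty gene list")
        return []
    scaled = raw / raw.max() * 100.0
    return scaled[scaled > threshold_pct].index.tolist()


def signature_auroc(
    compendium: Compendium,
    responses: pd.DataFrame,
    signature: Signature,
    n_perm: int = 1000,
    seed: int = 0,
) -> tuple[pd.Series, float, float]:
    """Score a fixed signature and test its high-vs-low discrimination.

    The per-sample score is mean log2 expression of the present up genes
    minus mean log2 expression of the present down genes (an empty side
    contributes 0); auROC is computed over pre-vaccination samples of
    high/low participants and its significance by label permutation:
    p = (1 + #{permuted auROC >= observed}) / (n_perm + 1).
    """
    genes = set(compendium.expression.index)
    up = [g for g in signature.up_genes if g in genes]
    down = [g for g in signature.down_genes if g in genes]
    if not up and not down:
        missing = sorted(set(signature.up_genes + signature.down_genes))
        raise KeyError(f"no signature gene present in the matrix; missing: {missing}")

    expr = compendium.expression
    score = pd.Series(0.0, index=expr.columns, name=f"score_{signature.name}")
    if up:
        score += expr.loc[up].mean(axis=0)
    if down:
        score -= expr.loc[down].mean(axis=0)

    labeled = responses[responses["responder"].isin(["high", "low"])]
    qualifying = _qualifying_samples(compendium, labeled)
    if qualifying.empty:
        raise ValueError("no pre-vaccination sample for any high/low participant")
    sample_labels = (
        labeled.loc[qualifying["participant_id"], "responder"].eq("high").astype(int).to_numpy()
    )
    sample_scores = score.loc[qualifying.index].to_numpy()
    if len(np.unique(sample_labels)) < 2:
        raise ValueError("both classes must be present")
    observed = auroc(sample_scores, sample_labels)

    rng = np.random.default_rng(seed)
    perm_labels = sample_labels.copy()
    count = 0
    for _ in range(n_perm):
        rng.shuffle(perm_labels)
        if auroc(sample_scores, perm_labels) >= observed:
            count += 1
    p = (1 + count) / (n_perm + 1)
    return score, observed, p
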