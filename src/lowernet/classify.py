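"""VS/UWS vs MCS classification: LASSO-penalized logistic models with CV.

Five imaging feature sets are built per scope (one network or all four):

1. rs-fMRI rating -- 2 scores per node (ICA rating, SBA rating),
2. rs-fMRI map intensity -- 2 scores per node (ICA, SBA mean intensity),
3. MRI rating -- 1 structural score per node,
4. = 1 + 3 (3 scores per node),
5. = 2 + 3 (3 scores per node),

each with and without a clinical covariate block (etiology dummy-coded with
traumatic as reference, disease duration, age), plus a clinical-only
baseline.  Variable selection uses the LASSO (L1) penalty with the penalty
weight chosen by inner stratified 10-fold cross-validation maximizing
out-of-fold log-likelihood.  Validation is leave-one-out (or stratified
10-fold) cross-validation in which the *entire* pipeline -- standardization,
penalty selection, fit -- is re-run on each training split, so no
information leaks from the held-out subject.

MCS is the positive class throughout; sensitivity is the MCS detection rate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

logger = logging.getLogger(__name__)

POSITIVE_CLASS = "MCS"  # diagnosis coded 1
NEGATIVE_CLASS = "VS/UWS"
DEFAULT_CS = np.logspace(-2.0, 2.0, 11)
CLINICAL_COLUMNS = ("etiology_vascular", "etiology_anoxic", "disease_duration_months", "age_years")

MODEL_IDS = ("rating", "intensity", "mri", "rating+mri", "intensity+mri")


# ---------------------------------------------------------------------------
# Feature tables
# ---------------------------------------------------------------------------


@dataclass
class FeatureTable:
    model_id: str
    scope: str  # "SM" | "AUD" | "LVIS" | "MVIS" | "all4" | "clinical"
    x: pd.DataFrame
    y: np.ndarray  # 1 = MCS, 0 = VS/UWS
    subject_ids: list[str]
    column_hemisphere: dict[str, str]  # imaging column -> "L" | "R"


def build_feature_models(
    profiles: list,
    records: list,
    model,
    scope: str = "all4",
    include_clinical_baseline: bool = True,
) -> dict[str, FeatureTable]:
    """All feature tables for one scope from subject profiles and records.

    ``profiles`` are :class:`~lowernet.scoring.PatientNetworkProfile`;
    ``records`` the matching :class:`~lowernet.synthcohort.SubjectRecord`
    (VS/UWS and MCS rows only -- any other diagnosis raises); ``model`` is
    the :class:`~lowernet.networks.NetworkModel`.  Returns tables keyed
    ``"<model_id>"``, ``"<model_id>+clinical"`` and (optionally)
    ``"clinical"``.
    """
    from .networks import NETWORK_NAMES

    for r in records:
        if r.diagnosis not in (POSITIVE_CLASS, NEGATIVE_CLASS):
            raise ValueError(
                f"{r.subject_id}: diagnosis {r.diagnosis!r} not allowed in "
                "classification rows (filter SD/control first)"
            )
    nets = list(NETWORK_NAMES) if scope == "all4" else [scope]
    nodes = [nd for net in nets for nd in model.nodes(net)]

    y = np.array([1 if r.diagnosis == POSITIVE_CLASS else 0 for r in records])
    sids = [r.subject_id for r in records]

    def imaging_block(model_id: str) -> tuple[pd.DataFrame, dict[str, str]]:
        cols: dict[str, list[float]] = {}
        hemi: dict[str, str] = {}
        for nd in nodes:
            if model_id in ("rating", "rating+mri"):
                for meth in ("ICA", "SBA"):
                    name = f"rating_{meth}_{nd.name}"
                    cols[name] = [p.ratings[nd.name][meth] for p in profiles]
                    hemi[name] = nd.hemisphere
            if model_id in ("intensity", "intensity+mri"):
                for meth in ("ICA", "SBA"):
                    name = f"intensity_{meth}_{nd.name}"
                    cols[name] = [p.intensities[nd.name][meth] for p in profiles]
                    hemi[name] = nd.hemisphere
            if model_id in ("mri", "rating+mri", "intensity+mri"):
                name = f"mri_{nd.name}"
                cols[name] = [r.mri_node_ratings[nd.name] for r in records]
                hemi[name] = nd.hemisphere
        return pd.DataFrame(cols, index=sids), hemi

    def clinical_block() -> pd.DataFrame:
        return pd.DataFrame(
            {
                "etiology_vascular": [1.0 if r.etiology == "vascular" else 0.0 for r in records],
                "etiology_anoxic": [1.0 if r.etiology == "anoxic" else 0.0 for r in records],
                "disease_duration_months": [r.disease_duration_months for r in records],
                "age_years": [float(r.age_years) for r in records],
            },
            index=sids,
        )

    tables: dict[str, FeatureTable] = {}
    for mid in MODEL_IDS:
        xi, hemi = imaging_block(mid)
        tables[mid] = FeatureTable(mid, scope, xi, y, sids, hemi)
        xc = pd.concat([xi, clinical_block()], axis=1)
        tables[mid + "+clinical"] = FeatureTable(mid + "+clinical", scope, xc, y, sids, hemi)
    if include_clinical_baseline:
        tables["clinical"] = FeatureTable("clinical", "clinical", clinical_block(), y, sids, {})
    return tables


# ---------------------------------------------------------------------------
# Penalized fit
# ---------------------------------------------------------------------------


@dataclass
class FittedLasso:
    coef: np.ndarray  # on the original (unstandardized) scale
    intercept: float
    columns: list[str]
    selected: list[str]
    chosen_c: float
    flags: list[str] = field(default_factory=list)

    def predict_proba(self, x: pd.DataFrame | np.ndarray) -> np.ndarray:
        xa = np.asarray(x, dtype=float)
        logits = xa @ self.coef + self.intercept
        return 1.0 / (1.0 + np.exp(-logits))


def _fit_l1(x: np.ndarray, y: np.ndarray, c: float, tol: float = 1e-9) -> tuple[np.ndarray, float]:
    clf = LogisticRegression(
        l1_ratio=1.0,
        C=c,
        solver="liblinear",
        intercept_scaling=1e4,  # keeps the intercept effectively unpenalized
        tol=tol,
        max_iter=int(1e6),
        random_state=0,
    )
    clf.fit(x, y)
    return clf.coef_[0].copy(), float(clf.intercept_[0])


def _oof_loglik(x: np.ndarray, y: np.ndarray, c: float, folds) -> float:
    ll = 0.0
    for train, test in folds:
        # looser tolerance: penalty selection only needs the ranking of C values
        coef, b = _fit_l1(x[train], y[train], c, tol=1e-6)
        p = 1.0 / (1.0 + np.exp(-(x[test] @ coef + b)))
        p = np.clip(p, 1e-12, 1 - 1e-12)
        ll += float(np.sum(y[test] * np.log(p) + (1 - y[test]) * np.log(1 - p)))
    return ll


def _inner_folds(y: np.ndarray, rng_seed: int, n_splits: int = 10):
    """Stratified folds for penalty selection; falls back to leave-pair-out
    when a class is too small to stratify."""
    counts = np.bincount(y, minlength=2)
    k = int(min(n_splits, counts.min()))
    if k >= 2:
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=rng_seed)
        return list(skf.split(np.zeros(len(y)), y))
    logger.info("inner CV falling back to leave-pair-out (class counts %s)", counts.tolist())
    pos = np.flatnonzero(y == 1)
    neg = np.flatnonzero(y == 0)
    folds = []
    for i in pos:
        for j in neg:
            test = np.array([i, j])
            train = np.setdiff1d(np.arange(len(y)), test)
            folds.append((train, test))
    return folds


def lasso_logistic_cv(
    features: pd.DataFrame | np.ndarray,
    labels: np.ndarray,
    rng_seed: int = 0,
    cs: np.ndarray | None = None,
    penalty_override: float | None = None,
    column_hemisphere: dict[str, str] | None = None,
) -> FittedLasso:
    """L1-penalized logistic regression with inner-CV penalty selection.

    Columns are standardized (mean 0, sd 1) before penalization; reported
    coefficients are mapped back to the original scale.  ``penalty_override``
    fixes the inverse penalty weight C directly (C -> 0 is the infinite-
    penalty limit, C -> inf the unpenalized limit).  If no variable is
    retained the model degrades to intercept-only prediction of the training
    prevalence, flagged ``no_variables_retained``.
    """
    if isinstance(features, pd.DataFrame):
        columns = list(features.columns)
        xa = features.to_numpy(dtype=float)
    else:
        xa = np.asarray(features, dtype=float)
        columns = [f"x{i}" for i in range(xa.shape[1])]
    y = np.asarray(labels, dtype=int)
    counts = np.bincount(y, minlength=2)
    if counts.min() < 2:
        raise ValueError(f"need >= 2 patients per class, got counts {counts.tolist()}")

    mu = xa.mean(axis=0)
    sd = xa.std(axis=0)
    sd_safe = np.where(sd > 0, sd, 1.0)
    xs = (xa - mu) / sd_safe

    flags: list[str] = []
    if penalty_override is not None:
        best_c = float(penalty_override)
    else:
        grid = DEFAULT_CS if cs is None else np.asarray(cs, dtype=float)
        folds = _inner_folds(y, rng_seed)
        lls = [_oof_loglik(xs, y, c, folds) for c in grid]
        best_c = float(grid[int(np.argmax(lls))])

    coef_s, intercept = _fit_l1(xs, y, best_c)
    selected = [columns[j] for j in np.flatnonzero(coef_s != 0)]
    if not selected:
        flags.append("no_variables_retained")
        prev = np.clip(y.mean(), 1e-6, 1 - 1e-6)
        coef_s = np.zeros_like(coef_s)
        intercept = float(np.log(prev / (1 - prev)))
    coef = coef_s / sd_safe
    intercept = intercept - float(mu @ coef)
    return FittedLasso(coef, intercept, columns, selected, best_c, flags)


def hemisphere_counts(selected: list[str], column_hemisphere: dict[str, str]) -> tuple[int, int]:
    l = sum(1 for c in selected if column_hemisphere.get(c) == "L")
    r = sum(1 for c in selected if column_hemisphere.get(c) == "R")
    return l, r


# ---------------------------------------------------------------------------
# Cross-validated evaluation
# ---------------------------------------------------------------------------


@dataclass
class ModelResult:
    model_id: str
    cv: str
    n: int
    probabilities: np.ndarray
    predicted: np.ndarray
    accuracy: float
    balanced_accuracy: float
    auc: float  # NaN when the model predicts constantly
    sensitivity: float
    specificity: float
    sensitivity_ci: tuple[float, float]
    specificity_ci: tuple[float, float]
    selected_variables: list[str]
    n_left: int
    n_right: int
    false_positive_ids: list[str]
    false_negative_ids: list[str]
    auc_band: str
    flags: list[str] = field(default_factory=list)


def _confusion_metrics(y: np.ndarray, pred: np.ndarray) -> tuple[float, float, float, float]:
    tp = int(np.sum((pred == 1) & (y == 1)))
    fn = int(np.sum((pred == 0) & (y == 1)))
    tn = int(np.sum((pred == 0) & (y == 0)))
    fp = int(np.sum((pred == 1) & (y == 0)))
    sens = tp / (tp + fn) if tp + fn else np.nan
    spec = tn / (tn + fp) if tn + fp else np.nan
    acc = (tp + tn) / len(y)
    bal = (sens + spec) / 2.0
    return acc, bal, sens, spec


def evaluate_cv(
    table: FeatureTable,
    rng_seed: int = 0,
    cv: str = "loocv",
    n_boot: int = 2000,
    cs: np.ndarray | None = None,
) -> ModelResult:
    """LOOCV (or stratified 10-fold) evaluation with full refit per fold."""
    x = table.x.to_numpy(dtype=float)
    y = table.y
    n = len(y)
    if n < 10:
        raise ValueError("need at least 10 patients for cross-validated evaluation")
    if cv == "loocv":
        folds = [(np.delete(np.arange(n), i), np.array([i])) for i in range(n)]
    elif cv == "10fold":
        k = int(min(10, np.bincount(y, minlength=2).min()))
        skf = StratifiedKFold(n_splits=max(k, 2), shuffle=True, random_state=rng_seed)
        folds = list(skf.split(np.zeros(n), y))
    else:
        raise ValueError(f"unknown cv scheme {cv!r}")

    probs = np.zeros(n)
    auc_scores = np.zeros(n)
    for train, test in folds:
        fit = lasso_logistic_cv(
            pd.DataFrame(x[train], columns=table.x.columns), y[train], rng_seed=rng_seed, cs=cs
        )
        probs[test] = fit.predict_proba(x[test])
        # an intercept-only fold predicts the training prevalence for everyone:
        # that probability encodes the training fold's class balance, not the
        # held-out patient, and (pooled over leave-one-out folds) would rank
        # every held-out positive below every held-out negative.  For the rank
        # statistic such folds are ties at 0.5.
        auc_scores[test] = 0.5 if not fit.selected else probs[test]

    pred = (probs > 0.5).astype(int)
    acc, bal, sens, spec = _confusion_metrics(y, pred)
    flags: list[str] = []
    if np.ptp(auc_scores) == 0:
        auc = float("nan")
        flags.append("constant_predictions_auc_undefined")
    else:
        auc = float(roc_auc_score(y, auc_scores))
    sens_ci, spec_ci = bootstrap_sens_spec(pred, y, n_boot=n_boot, rng_seed=rng_seed)

    # variables reported from the final model fitted on the full data
    full_fit = lasso_logistic_cv(table.x, y, rng_seed=rng_seed, cs=cs)
    n_l, n_r = hemisphere_counts(full_fit.selected, table.column_hemisphere)
    flags.extend(full_fit.flags)

    sid = np.asarray(table.subject_ids)
    return ModelResult(
        model_id=table.model_id,
        cv=cv,
        n=n,
        probabilities=probs,
        predicted=pred,
        accuracy=acc,
        balanced_accuracy=bal,
        auc=auc,
        sensitivity=sens,
        specificity=spec,
        sensitivity_ci=sens_ci,
        specificity_ci=spec_ci,
        selected_variables=full_fit.selected,
        n_left=n_l,
        n_right=n_r,
        false_positive_ids=sid[(pred == 1) & (y == 0)].tolist(),
        false_negative_ids=sid[(pred == 0) & (y == 1)].tolist(),
        auc_band=auc_band(auc) if np.isfinite(auc) else "undefined",
        flags=flags,
    )


def bootstrap_sens_spec(
    predictions: np.ndarray,
    labels: np.ndarray,
    n_boot: int = 2000,
    rng_seed: int = 0,
) -> tuple[tuple[float, float], tuple[float, float]]:
    """Percentile 95% CIs for sensitivity and specificity from stratified
    bootstrap resamples (resampling within each class)."""
    pred = np.asarray(predictions, dtype=int)
    y = np.asarray(labels, dtype=int)
    pos = np.flatnonzero(y == 1)
    neg = np.flatnonzero(y == 0)
    if len(pos) < 2 or len(neg) < 2:
        raise ValueError("each class needs >= 2 members for the stratified bootstrap")
    rng = np.random.default_rng(rng_seed)
    sens = np.empty(n_boot)
    spec = np.empty(n_boot)
    for b in range(n_boot):
        ip = rng.choice(pos, size=len(pos), replace=True)
        ineg = rng.choice(neg, size=len(neg), replace=True)
        sens[b] = np.mean(pred[ip] == 1)
        spec[b] = np.mean(pred[ineg] == 0)
    return (
        (float(np.percentile(sens, 2.5)), float(np.percentile(sens, 97.5))),
        (float(np.percentile(spec, 2.5)), float(np.percentile(spec, 97.5))),
    )


def mcnemar_compare(preds_a: np.ndarray, preds_b: np.ndarray, labels: np.ndarray) -> float:
    """McNemar test on the discordant pairs of two classifiers.

    Exact binomial when the discordant count is <= 25, chi-square with
    continuity correction otherwise; p = 1 with no discordant pairs.
    """
    a_ok = np.asarray(preds_a) == np.asarray(labels)
    b_ok = np.asarray(preds_b) == np.asarray(labels)
    if len(a_ok) != len(b_ok):
        raise ValueError("prediction vectors must cover the same patients")
    n01 = int(np.sum(a_ok & ~b_ok))
    n10 = int(np.sum(~a_ok & b_ok))
    n_disc = n01 + n10
    if n_disc == 0:
        return 1.0
    from statsmodels.stats.contingency_tables import mcnemar as sm_mcnemar

    table = [[0, n01], [n10, 0]]
    if n_disc <= 25:
        res = sm_mcnemar(table, exact=True)
    else:
        res = sm_mcnemar(table, exact=False, correction=True)
    return float(min(1.0, res.pvalue))


def auc_band(auc: float) -> str:
    """Diagnostic-quality label; band boundaries belong to the higher band
    (an AUC of 0.80 reads 'very good')."""
    if not 0.0 <= auc <= 1.0:
        raise ValueError("AUC must lie in [0, 1]")
    if auc >= 0.8:
        return "very good"
    if auc >= 0.7:
        return "good"
    if auc >= 0.6:
        return "sufficient"
    return "bad"


def classify_by_etiology(
    table: FeatureTable,
    etiology: list[str] | np.ndarray,
    rng_seed: int = 0,
    min_per_class: int = 5,
    n_boot: int = 500,
) -> dict[str, ModelResult | dict]:
    """Re-run the cross-validated evaluation within each etiology stratum.

    Strata with only one class are flagged and skipped; strata with fewer
    than ``min_per_class`` patients in either class are evaluated but
    flagged ``underpowered``.
    """
    et = np.asarray(etiology)
    out: dict[str, ModelResult | dict] = {}
    for stratum in ("traumatic", "vascular", "anoxic"):
        idx = np.flatnonzero(et == stratum)
        if len(idx) == 0:
            continue
        y = table.y[idx]
        counts = np.bincount(y, minlength=2)
        if counts.min() == 0:
            out[stratum] = {"flag": "single_class", "n": int(len(idx))}
            continue
        if counts.min() < 2 or len(idx) < 10:
            out[stratum] = {"flag": "underpowered", "n": int(len(idx))}
            continue
        sub = FeatureTable(
            table.model_id,
            table.scope,
            table.x.iloc[idx],
            y,
            [table.subject_ids[i] for i in idx],
            table.column_hemisphere,
        )
        res = evaluate_cv(sub, rng_seed=rng_seed, n_boot=n_boot)
        if counts.min() < min_per_class:
            res.flags.append("underpowered")
        out[stratum] = res
    return out


def results_table(results: list[ModelResult]) -> pd.DataFrame:
    """Summary table with ACCU / Bal ACCU / AUC / L / R columns (undefined
    AUC rendered as 0, matching the conventional table shape)."""
    rows = []
    for r in results:
        rows.append(
            {
                "model": r.model_id,
                "ACCU": round(r.accuracy, 2),
                "Bal_ACCU": round(r.balanced_accuracy, 2),
                "AUC": 0.0 if not np.isfinite(r.auc) else round(r.auc, 2),
                "L": r.n_left,
                "R": r.n_right,
            }
        )
    return pd.DataFrame(rows)
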