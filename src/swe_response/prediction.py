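"""Leave-one-out cross-validated response prediction.

Six preset models mirror the study design.  The three "noninvasive" models
combine SWE features per visit — visit 1: {E_mean_ratio1, s1}; visit 2:
{E_mean2, s2}; visit 3: {E_max_ratio3, f_mass3} — over all patients; the
three "mixed" models add the Ki-67 index and are fit on ER-positive tumors
only.  Each model is evaluated by leave-one-out cross-validation (LOOCV):
for every complete-case patient an unpenalized logistic regression is fit on
the remaining patients and the held-out responder probability is recorded.
The out-of-fold probabilities feed a threshold-sweep ROC, trapezoidal AUC
(equal to the tie-aware Mann-Whitney concordance), a stratified-bootstrap
percentile confidence interval, and the operating point closest to the
perfect corner (0, 1).  Paired AUCs are compared with DeLong's test on the
shared patients.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_curve

__all__ = [
    "ModelSpec",
    "ModelResult",
    "MODEL_SPECS",
    "loocv_probabilities",
    "roc_and_auc",
    "auc_confidence_interval",
    "optimal_cutoff",
    "compare_aucs",
    "run_model_suite",
    "feature_matrix",
    "rank_auc",
]


@dataclass(frozen=True)
class ModelSpec:
    name: str
    features: tuple
    visit: int
    er_positive_only: bool = False


#: the six preset models (noninvasive per visit; mixed = + Ki-67, ER+ subset)
MODEL_SPECS = (
    ModelSpec("noninvasive_v1", ("e_mean_ratio_1", "mass_size_mm_1"), 1),
    ModelSpec("noninvasive_v2", ("e_mean_2", "mass_size_mm_2"), 2),
    ModelSpec("noninvasive_v3", ("e_max_ratio_3", "f_mass_3"), 3),
    ModelSpec("mixed_v1", ("e_mean_ratio_1", "mass_size_mm_1", "ki67_pct"), 1, True),
    ModelSpec("mixed_v2", ("e_mean_2", "mass_size_mm_2", "ki67_pct"), 2, True),
    ModelSpec("mixed_v3", ("e_max_ratio_3", "f_mass_3", "ki67_pct"), 3, True),
)


@dataclass
class ModelResult:
    name: str
    patient_ids: np.ndarray
    probabilities: np.ndarray   # out-of-fold responder probabilities
    y: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float
    auc_ci: tuple = (float("nan"), float("nan"))
    cutoff: float = float("nan")
    sensitivity: float = float("nan")
    specificity: float = float("nan")

    @property
    def n_used(self) -> int:
        return int(self.y.size)


class SeparationWarning(UserWarning):
    """Perfect separation in a logistic fit; a ridge-stabilized fit was used."""


def _fit_logistic(X: np.ndarray, y: np.ndarray) -> LogisticRegression:
    """Maximum-likelihood logistic fit; ridge-stabilized on separation.

    Features are standardized internally for numerical stability (the
    unpenalized optimum is affine-equivariant, so predictions are unchanged).
    """
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    Xs = (X - mu) / sd
    clf = LogisticRegression(
        C=np.inf, solver="newton-cholesky", tol=1e-12, max_iter=500
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        clf.fit(Xs, y)
    # on standardized features a genuine MLE slope beyond ~30 (odds ratio
    # e^30 per SD) only arises under (quasi-)separation
    if np.abs(clf.coef_).max() > 30.0 or clf.n_iter_[0] >= 500:
        warnings.warn(
            "perfect separation in logistic fit; using ridge-stabilized fit",
            SeparationWarning,
            stacklevel=3,
        )
        clf = LogisticRegression(
            C=1e3, solver="newton-cholesky", tol=1e-12, max_iter=500
        )
        clf.fit(Xs, y)
    clf._scale = (mu, sd)
    return clf


def _predict_proba(clf: LogisticRegression, X: np.ndarray) -> np.ndarray:
    mu, sd = clf._scale
    return clf.predict_proba((X - mu) / sd)[:, 1]


def loocv_probabilities(X, y) -> np.ndarray:
    """Out-of-fold responder probability for each sample.

    Sample i's probability comes from a logistic regression fit on all other
    samples; deterministic given (X, y).  Requires complete cases, n >= 10,
    and both classes in every training fold.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    if X.ndim != 2 or X.shape[0] != y.size:
        raise ValueError("X must be 2-D with one row per label")
    if np.isnan(X).any():
        raise ValueError("X must be complete cases (no NaN)")
    n = y.size
    if n < 10:
        raise ValueError(f"LOOCV needs at least 10 samples, got {n}")
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    probs = np.empty(n)
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        y_train = y[mask]
        if len(np.unique(y_train)) < 2:
            raise ValueError(f"training fold without both classes (held out {i})")
        clf = _fit_logistic(X[mask], y_train)
        probs[i] = _predict_proba(clf, X[i : i + 1])[0]
    return probs


def rank_auc(scores, y) -> float:
    """Mann-Whitney concordance AUC with ties counted 1/2 (rank formula)."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y).astype(int)
    n_pos = int(y.sum())
    n_neg = y.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    ranks = stats.rankdata(scores)
    return float(
        (ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)
    )


def roc_and_auc(probs, y, name: str = "model", patient_ids=None) -> ModelResult:
    """ROC by threshold sweep over the scores; AUC by the trapezoidal rule."""
    probs = np.asarray(probs, dtype=float)
    y = np.asarray(y).astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    fpr, tpr, thresholds = roc_curve(y, probs, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    if patient_ids is None:
        patient_ids = np.arange(y.size)
    return ModelResult(
        name=name,
        patient_ids=np.asarray(patient_ids),
        probabilities=probs,
        y=y,
        fpr=fpr,
        tpr=tpr,
        thresholds=thresholds,
        auc=auc,
    )


def auc_confidence_interval(
    probs,
    y,
    level: float = 0.95,
    n_boot: int = 2000,
    seed: Optional[int] = None,
) -> tuple:
    """Stratified-bootstrap percentile interval for the AUC.

    Resamples positives and negatives separately ``n_boot`` times; the
    interval is widened to contain the point estimate (percentile intervals
    on small samples can otherwise exclude it by discreteness).
    """
    if n_boot < 100:
        warnings.warn("fewer than 100 bootstrap resamples gives unstable intervals")
    probs = np.asarray(probs, dtype=float)
    y = np.asarray(y).astype(int)
    rng = np.random.default_rng(seed)
    pos = probs[y == 1]
    neg = probs[y == 0]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both classes must be present")
    aucs = np.empty(n_boot)
    for b in range(n_boot):
        p = rng.choice(pos, size=pos.size, replace=True)
        q = rng.choice(neg, size=neg.size, replace=True)
        scores = np.concatenate([p, q])
        labels = np.concatenate([np.ones(pos.size, int), np.zeros(neg.size, int)])
        aucs[b] = rank_auc(scores, labels)
    alpha = 1.0 - level
    lo, hi = np.quantile(aucs, [alpha / 2.0, 1.0 - alpha / 2.0])
    point = rank_auc(probs, y)
    return (float(min(lo, point)), float(max(hi, point)))


def optimal_cutoff(result: ModelResult) -> dict:
    """Operating point closest to (0, 1) on the ROC curve.

    Minimizes sqrt((1 - sens)^2 + (1 - spec)^2); ties broken by higher
    sensitivity, then by higher threshold.  Returns the probability
    threshold with its sensitivity and specificity.
    """
    fpr, tpr, thr = result.fpr, result.tpr, result.thresholds
    if fpr.size == 0:
        raise ValueError("empty ROC")
    dist = np.hypot(1.0 - tpr, fpr)
    order = sorted(
        range(fpr.size), key=lambda i: (dist[i], -tpr[i], -thr[i])
    )
    best = order[0]
    # roc_curve's first threshold is inf (no positives predicted); report it
    # as a cutoff just above the largest score
    threshold = float(thr[best])
    if math.isinf(threshold):
        threshold = float(result.probabilities.max()) + 1e-12
    return {
        "threshold": threshold,
        "sensitivity": float(tpr[best]),
        "specificity": float(1.0 - fpr[best]),
    }


# ---------------------------------------------------------------------------
# DeLong paired AUC comparison
# ---------------------------------------------------------------------------

def _midrank_placements(pos: np.ndarray, neg: np.ndarray):
    """DeLong structural components V10 (per positive) and V01 (per negative)."""
    m, n = pos.size, neg.size
    all_scores = np.concatenate([pos, neg])
    rank_all = stats.rankdata(all_scores)
    rank_pos = stats.rankdata(pos)
    rank_neg = stats.rankdata(neg)
    v10 = (rank_all[:m] - rank_pos) / n
    v01 = 1.0 - (rank_all[m:] - rank_neg) / m
    return v10, v01


def compare_aucs(result_a: ModelResult, result_b: ModelResult) -> float:
    """Two-sided DeLong test for paired AUCs on the shared patients.

    Both models' out-of-fold probabilities are restricted to the patients
    they have in common (with identical labels there).  Returns the p-value;
    identical restricted score vectors give p = 1.
    """
    ids_a = {pid: i for i, pid in enumerate(result_a.patient_ids)}
    shared = [pid for pid in result_b.patient_ids if pid in ids_a]
    if len(shared) < 10:
        warnings.warn(f"only {len(shared)} shared samples in AUC comparison")
    idx_a = np.array([ids_a[pid] for pid in shared])
    ids_b = {pid: i for i, pid in enumerate(result_b.patient_ids)}
    idx_b = np.array([ids_b[pid] for pid in shared])
    y = result_a.y[idx_a]
    if not np.array_equal(y, result_b.y[idx_b]):
        raise ValueError("labels disagree on shared patients")
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present among shared patients")

    pa, pb = result_a.probabilities[idx_a], result_b.probabilities[idx_b]
    pos_mask = y == 1
    m, n = int(pos_mask.sum()), int((~pos_mask).sum())
    v10 = np.empty((2, m))
    v01 = np.empty((2, n))
    aucs = np.empty(2)
    for k, scores in enumerate((pa, pb)):
        v10[k], v01[k] = _midrank_placements(scores[pos_mask], scores[~pos_mask])
        aucs[k] = v10[k].mean()
    s10 = np.cov(v10) if m > 1 else np.zeros((2, 2))
    s01 = np.cov(v01) if n > 1 else np.zeros((2, 2))
    cov = s10 / m + s01 / n
    var_diff = cov[0, 0] + cov[1, 1] - 2.0 * cov[0, 1]
    if var_diff <= 0:
        return 1.0 if math.isclose(aucs[0], aucs[1], abs_tol=1e-12) else 0.0
    z = (aucs[0] - aucs[1]) / math.sqrt(var_diff)
    return float(2.0 * stats.norm.sf(abs(z)))


# ---------------------------------------------------------------------------
# model suite over a cohort feature matrix
# ---------------------------------------------------------------------------

def feature_matrix(
    features: pd.DataFrame,
    pathology: pd.DataFrame,
) -> pd.DataFrame:
    """Wide per-patient matrix: visit-suffixed features + Ki-67/ER + label."""
    wide = features.pivot(index="patient_id", columns="visit")
    wide.columns = [f"{var}_{int(v)}" for var, v in wide.columns]
    pat = pathology.set_index("patient_id")
    cols = ["ki67_pct", "er_pos", "responder"]
    return wide.join(pat[cols]).reset_index()


def run_model_suite(
    matrix: pd.DataFrame,
    specs: Sequence[ModelSpec] = MODEL_SPECS,
    ci_boot: int = 2000,
    seed: Optional[int] = None,
    min_cases: int = 10,
) -> dict:
    """Run the preset models; returns ``{name: ModelResult}``.

    Each model uses complete cases for its own features (and, for mixed
    models, the ER-positive subset).  Presets with fewer than ``min_cases``
    complete cases are skipped with a warning.
    """
    results: dict = {}
    for spec in specs:
        sub = matrix
        if spec.er_positive_only:
            sub = sub[sub["er_pos"].astype(bool)]
        cols = list(spec.features)
        sub = sub.dropna(subset=cols + ["responder"])
        if len(sub) < min_cases:
            warnings.warn(
                f"model {spec.name}: only {len(sub)} complete cases; skipped"
            )
            continue
        X = sub[cols].to_numpy(dtype=float)
        y = sub["responder"].to_numpy(dtype=bool).astype(int)
        probs = loocv_probabilities(X, y)
        res = roc_and_auc(
            probs, y, name=spec.name, patient_ids=sub["patient_id"].to_numpy()
        )
        res.auc_ci = auc_confidence_interval(probs, y, n_boot=ci_boot, seed=seed)
        cut = optimal_cutoff(res)
        res.cutoff = cut["threshold"]
        res.sensitivity = cut["sensitivity"]
        res.specificity = cut["specificity"]
        results[spec.name] = res
    return results


def summarize_model_suite(results: dict) -> pd.DataFrame:
    """AUC / CI / cutoff / specificity / sensitivity per model (report shape)."""
    rows = []
    for name, r in results.items():
        rows.append(
            {
                "model": name,
                "n": r.n_used,
                "auc": r.auc,
                "auc_ci_lo": r.auc_ci[0],
                "auc_ci_hi": r.auc_ci[1],
                "cutoff": r.cutoff,
                "specificity": r.specificity,
                "sensitivity": r.sensitivity,
            }
        )
    return pd.DataFrame(rows)
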