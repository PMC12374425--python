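"""Nested leave-one-out diagnostic classifier and performance reporting.

The classifier is an unregularized logistic regression whose features
are chosen, inside every training fold, by a minimum-redundancy
maximum-relevance (mRMR) filter followed by sequential forward selection
(SFS) scored by inner leave-one-out accuracy.  The whole selection +
fitting procedure is repeated for each held-out subject (nested
leave-one-out cross-validation), so the out-of-fold probabilities are
free of selection bias.  Performance is summarized by sensitivity,
specificity, accuracy, precision and F1, each binomial proportion with
an exact Clopper-Pearson confidence interval, at both the default 0.5
probability threshold and a threshold optimized as the ROC point closest
to (0, 1).

Numerical notes
---------------
Logistic fits use Newton-Raphson with a tiny Hessian ridge (1e-8) for
solvability and an L-infinity coefficient cap (default 15 on the
standardized scale) that keeps separated fits finite; a capped fit is
recorded.  Inner leave-one-out fits are solved for all held-out samples
simultaneously by a batched Newton iteration, which is what makes the
nested scheme affordable at cohort scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

_RIDGE = 1e-8


# ---------------------------------------------------------------------------
# Task definitions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TaskDefinition:
    """Binary diagnostic task: how manifest diagnoses map to the two sides.

    The small vascular groups (mixed Alzheimer's and pure vascular
    cognitive dysfunction) are merged into one CVD class; all patient
    groups merge into "disease" against healthy controls.
    """

    name: str
    positive: str
    mapping: dict  # diagnosis -> class name; absent diagnoses are excluded

    def labels(self, diagnoses: Sequence[str]
               ) -> tuple[np.ndarray, np.ndarray]:
        """(y, include_mask) for a vector of manifest diagnoses."""
        diagnoses = np.asarray(diagnoses, dtype=object)
        mapped = np.array([self.mapping.get(d) for d in diagnoses],
                          dtype=object)
        include = mapped != None  # noqa: E711  (elementwise)
        y = np.zeros(len(diagnoses), dtype=int)
        y[include] = (mapped[include] == self.positive).astype(int)
        return y[include], include


TASKS: dict[str, TaskDefinition] = {
    "AD_vs_HC": TaskDefinition(
        "AD_vs_HC", "AD", {"AD": "AD", "HC": "HC"}),
    "HC_vs_disease": TaskDefinition(
        "HC_vs_disease", "disease",
        {"AD": "disease", "DLB": "disease", "MixedAD": "disease",
         "VCD": "disease", "HC": "HC"}),
    "AD_vs_DLB": TaskDefinition(
        "AD_vs_DLB", "DLB", {"AD": "AD", "DLB": "DLB"}),
    "AD_vs_CVD": TaskDefinition(
        "AD_vs_CVD", "CVD", {"AD": "AD", "MixedAD": "CVD", "VCD": "CVD"}),
}


@dataclass
class MLConfig:
    mrmr_k: int = 30
    sfs_max: int = 10
    sfs_min_gain: int = 3     # inner-LOO subjects a feature must add
    coef_cap: float = 15.0
    seed: int = 0


@dataclass
class ClassificationResult:
    subject_ids: list[str]
    y: np.ndarray
    probabilities: np.ndarray
    fold_features: list[list[str]]       # per outer fold
    fold_coefs: list[np.ndarray]         # standardized coefficients
    fold_intercepts: list[float]
    feature_names: list[str]
    config: dict
    threshold_default: float = 0.5
    threshold_optimized: float | None = None


# ---------------------------------------------------------------------------
# Logistic regression (unregularized Newton with coefficient cap)
# ---------------------------------------------------------------------------

from scipy.special import expit as _sigmoid  # numerically stable logistic


def fit_logistic(X: np.ndarray, y: np.ndarray, coef_cap: float = 15.0,
                 max_iter: int = 30, tol: float = 1e-9,
                 init: np.ndarray | None = None) -> np.ndarray:
    """Maximum-likelihood logistic fit; returns [intercept, coefs].

    On (quasi-)separation the Newton steps are capped at ``coef_cap`` in
    absolute value, yielding a large-but-finite fit.
    """
    n, p = X.shape
    Xa = np.hstack([np.ones((n, 1)), X])
    beta = np.zeros(p + 1) if init is None else np.asarray(init, dtype=float)
    capped = False
    for _ in range(max_iter):
        eta = Xa @ beta
        prob = _sigmoid(eta)
        w = prob * (1.0 - prob)
        grad = Xa.T @ (y - prob)
        hess = (Xa * w[:, None]).T @ Xa + _RIDGE * np.eye(p + 1)
        step = np.linalg.solve(hess, grad)
        new = np.clip(beta + step, -coef_cap, coef_cap)
        capped = capped or np.abs(beta + step).max() > coef_cap
        change = np.abs(new - beta).max()
        beta = new
        if change < tol:
            break
    if capped:
        logger.debug("logistic fit hit the coefficient cap (separation?)")
    return beta


def loocv_probabilities(X: np.ndarray, y: np.ndarray,
                        coef_cap: float = 15.0, max_iter: int = 25,
                        tol: float = 1e-6,
                        init: np.ndarray | None = None) -> np.ndarray:
    """Leave-one-out predicted probabilities of unregularized logistic fits.

    All n leave-one-out problems are solved simultaneously by a batched
    Newton iteration (problem j excludes sample j), warm-started from the
    full-data fit; the per-problem Hessians are assembled with one matrix
    product over the precomputed outer-product design.
    """
    n, p = X.shape
    d = p + 1
    Xa = np.hstack([np.ones((n, 1)), X])
    beta0 = fit_logistic(X, y, coef_cap=coef_cap, init=init)
    B = np.tile(beta0, (n, 1))                       # (problems, d)
    mask = 1.0 - np.eye(n)                            # row i, problem j
    eye = _RIDGE * np.eye(d)
    xx = (Xa[:, :, None] * Xa[:, None, :]).reshape(n, d * d)
    active = np.arange(n)                            # unconverged problems
    for _ in range(max_iter):
        eta = Xa @ B[active].T                       # (samples, active)
        prob = _sigmoid(eta)
        m = mask[:, active]
        w = prob * (1.0 - prob) * m
        resid = (y[:, None] - prob) * m
        grad = Xa.T @ resid                          # (d, active)
        hess = (xx.T @ w).T.reshape(active.size, d, d) + eye
        step = np.linalg.solve(hess, grad.T[..., None])[..., 0]
        new = np.clip(B[active] + step, -coef_cap, coef_cap)
        change = np.abs(new - B[active]).max(axis=1)
        B[active] = new
        active = active[change >= tol]
        if active.size == 0:
            break
    return _sigmoid(np.einsum("ij,ij->i", Xa, B))


# ---------------------------------------------------------------------------
# mRMR filter
# ---------------------------------------------------------------------------

def _discretize3(X: np.ndarray) -> np.ndarray:
    """Equal-frequency 3-bin codes per column (constant columns -> one bin)."""
    q = np.quantile(X, [1.0 / 3.0, 2.0 / 3.0], axis=0)
    return (X > q[0]).astype(np.int64) + (X > q[1]).astype(np.int64)


def _mi_from_counts(cnt: np.ndarray) -> np.ndarray:
    """Mutual information (nats) from joint-count arrays (..., a, b)."""
    n = cnt.sum(axis=(-2, -1), keepdims=True)
    p = cnt / np.maximum(n, 1)
    pa = p.sum(axis=-1, keepdims=True)
    pb = p.sum(axis=-2, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = p * (np.log(p) - np.log(pa * pb))
    return np.nansum(t, axis=(-2, -1))


def _mi_columns_vs(codes: np.ndarray, other: np.ndarray,
                   n_other: int) -> np.ndarray:
    """MI of every column of 3-bin ``codes`` against one coded vector."""
    n, p = codes.shape
    joint = codes * n_other + other[:, None]          # (n, p)
    flat = joint + (3 * n_other) * np.arange(p)[None, :]
    cnt = np.bincount(flat.ravel(), minlength=3 * n_other * p)
    return _mi_from_counts(cnt.reshape(p, 3, n_other))


def _first_argmax(scores: np.ndarray, tol: float = 1e-12) -> int:
    """Index of the first score within ``tol`` of the maximum, so exact
    ties (e.g. duplicated features) resolve by column order regardless of
    floating-point summation order."""
    return int(np.flatnonzero(scores >= scores.max() - tol)[0])


def mrmr_rank(X: np.ndarray, y: np.ndarray, k: int) -> list[int]:
    """Greedy mRMR (mutual-information difference) feature ranking.

    Features are discretized into three equal-frequency bins; the first
    pick maximizes relevance MI(f; y) and each later pick maximizes
    MI(f; y) minus the mean MI against already-selected features.  Ties
    go to the lowest column index.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    n, p = X.shape
    k = min(k, p)
    codes = _discretize3(X)
    rel = _mi_columns_vs(codes, np.asarray(y, dtype=np.int64), 2)
    selected = [_first_argmax(rel)]
    red_sum = np.zeros(p)
    for _ in range(k - 1):
        last = selected[-1]
        red_sum += _mi_columns_vs(codes, codes[:, last], 3)
        score = rel - red_sum / len(selected)
        score[selected] = -np.inf
        selected.append(_first_argmax(score))
    return selected


# ---------------------------------------------------------------------------
# Sequential forward selection
# ---------------------------------------------------------------------------

def sfs_select(X: np.ndarray, y: np.ndarray, candidates: Sequence[int],
               max_features: int = 10, coef_cap: float = 15.0,
               min_gain_subjects: int = 3) -> list[int]:
    """Forward selection scored by inner leave-one-out accuracy.

    Starts from the empty set (whose score is the majority-class rate)
    and adds, at each step, the candidate giving the largest improvement
    in leave-one-out accuracy of the logistic fit; stops when nothing
    improves or ``max_features`` is reached.  A candidate must classify
    at least ``min_gain_subjects`` additional subjects correctly to count
    as an improvement — a one-subject gain is within the noise of the
    leave-one-out estimate itself, and admitting it lets pure-noise
    features accumulate.  Ties go to the earlier candidate in mRMR order.
    """
    y = np.asarray(y, dtype=float)
    selected: list[int] = []
    best = max(y.mean(), 1.0 - y.mean())
    margin = (min_gain_subjects - 0.5) / len(y)
    remaining = list(candidates)
    beta_sel = np.array([np.log(max(y.mean(), 1e-12)
                                / max(1.0 - y.mean(), 1e-12))])
    while remaining and len(selected) < max_features:
        init = np.append(beta_sel, 0.0)   # warm start: new coef at zero
        accs = np.empty(len(remaining))
        for idx, c in enumerate(remaining):
            cols = selected + [c]
            probs = loocv_probabilities(X[:, cols], y, coef_cap=coef_cap,
                                        init=init)
            accs[idx] = np.mean((probs > 0.5) == (y > 0.5))
        j = int(np.argmax(accs))          # first max: earlier candidate wins
        if accs[j] > best + margin:
            best = float(accs[j])
            selected.append(remaining.pop(j))
            beta_sel = fit_logistic(X[:, selected], y, coef_cap=coef_cap)
        else:
            break
    return selected


# ---------------------------------------------------------------------------
# Nested leave-one-out cross-validation
# ---------------------------------------------------------------------------

def nested_loocv_predict(X: np.ndarray, y: np.ndarray,
                         feature_names: Sequence[str] | None = None,
                         subject_ids: Sequence[str] | None = None,
                         config: MLConfig | None = None,
                         ) -> ClassificationResult:
    """Out-of-fold probabilities with per-fold mRMR + SFS + logistic fit.

    For every held-out subject, standardization statistics, the mRMR
    ranking, the SFS choice and the final fit all use the remaining
    subjects only.
    """
    config = config or MLConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    n, p = X.shape
    if np.isnan(X).any():
        raise ValueError("feature matrix contains missing values")
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    names = list(feature_names) if feature_names is not None else [
        f"f{j}" for j in range(p)]
    sids = list(subject_ids) if subject_ids is not None else [
        f"S{i:03d}" for i in range(n)]

    probs = np.empty(n)
    fold_features: list[list[str]] = []
    fold_coefs: list[np.ndarray] = []
    fold_intercepts: list[float] = []
    for i in range(n):
        tr = np.ones(n, dtype=bool)
        tr[i] = False
        ytr = y[tr]
        if len(np.unique(ytr)) < 2:
            raise ValueError("a class is absent from a training fold")
        mu = X[tr].mean(axis=0)
        sd = X[tr].std(axis=0)
        sd[sd == 0] = 1.0
        Z = (X[tr] - mu) / sd
        ranked = mrmr_rank(Z, ytr, config.mrmr_k)
        sel = sfs_select(Z, ytr, ranked, max_features=config.sfs_max,
                         coef_cap=config.coef_cap,
                         min_gain_subjects=config.sfs_min_gain)
        zi = (X[i] - mu) / sd
        if sel:
            beta = fit_logistic(Z[:, sel], ytr, coef_cap=config.coef_cap)
            probs[i] = float(_sigmoid(np.concatenate(([1.0], zi[sel]))
                                      @ beta))
            fold_coefs.append(beta[1:].copy())
            fold_intercepts.append(float(beta[0]))
        else:
            # an empty selection carries no evidence; the training
            # prevalence would anti-correlate with the held-out label
            # (a leave-one-out artifact), so emit the uninformative 0.5
            probs[i] = 0.5
            fold_coefs.append(np.empty(0))
            fold_intercepts.append(0.0)
        fold_features.append([names[j] for j in sel])

    return ClassificationResult(
        subject_ids=sids, y=y, probabilities=probs,
        fold_features=fold_features, fold_coefs=fold_coefs,
        fold_intercepts=fold_intercepts, feature_names=names,
        config={"mrmr_k": config.mrmr_k, "sfs_max": config.sfs_max,
                "sfs_min_gain": config.sfs_min_gain,
                "coef_cap": config.coef_cap, "seed": config.seed},
    )


def leaky_loocv_predict(X: np.ndarray, y: np.ndarray,
                        config: MLConfig | None = None) -> np.ndarray:
    """Deliberately biased variant: feature selection on ALL subjects,
    then leave-one-out refits on the chosen set.

    Exists only as a negative control for the selection-bias regression
    test; never use for reporting.
    """
    config = config or MLConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    mu, sd = X.mean(axis=0), X.std(axis=0)
    sd[sd == 0] = 1.0
    Z = (X - mu) / sd
    ranked = mrmr_rank(Z, y, config.mrmr_k)
    sel = sfs_select(Z, y, ranked, max_features=config.sfs_max,
                     coef_cap=config.coef_cap,
                     min_gain_subjects=config.sfs_min_gain)
    if not sel:
        sel = ranked[:1]
    return loocv_probabilities(Z[:, sel], y.astype(float),
                               coef_cap=config.coef_cap)


def single_feature_baseline(feature: np.ndarray, y: np.ndarray,
                            subject_ids: Sequence[str] | None = None,
                            coef_cap: float = 15.0) -> ClassificationResult:
    """Leave-one-out logistic regression on one standardized feature."""
    x = np.asarray(feature, dtype=float).reshape(-1)
    y = np.asarray(y, dtype=int)
    if np.std(x) == 0:
        raise ValueError("baseline feature is constant")
    n = len(x)
    sids = list(subject_ids) if subject_ids is not None else [
        f"S{i:03d}" for i in range(n)]
    probs = np.empty(n)
    coefs, icpts = [], []
    for i in range(n):
        tr = np.ones(n, dtype=bool)
        tr[i] = False
        mu, sd = x[tr].mean(), x[tr].std()
        sd = sd if sd > 0 else 1.0
        beta = fit_logistic(((x[tr] - mu) / sd)[:, None], y[tr],
                            coef_cap=coef_cap)
        probs[i] = float(_sigmoid(beta[0] + beta[1] * (x[i] - mu) / sd))
        coefs.append(beta[1:].copy())
        icpts.append(float(beta[0]))
    return ClassificationResult(
        subject_ids=sids, y=y, probabilities=probs,
        fold_features=[["baseline"]] * n, fold_coefs=coefs,
        fold_intercepts=icpts, feature_names=["baseline"],
        config={"model": "single_feature"},
    )


# ---------------------------------------------------------------------------
# Threshold optimization and performance metrics
# ---------------------------------------------------------------------------

def optimal_threshold(probs: np.ndarray, y: np.ndarray) -> float:
    """Probability threshold minimizing distance to the ROC corner (0, 1).

    Candidates are 0, 1 and the midpoints between sorted distinct
    probabilities; predictions are positive when prob > threshold; ties
    in distance go to the lower threshold.
    """
    probs = np.asarray(probs, dtype=float)
    y = np.asarray(y, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    uniq = np.unique(probs)
    cands = np.concatenate(([0.0], (uniq[:-1] + uniq[1:]) / 2.0, [1.0]))
    npos = int(y.sum())
    nneg = len(y) - npos
    best_thr, best_d = 0.0, np.inf
    for thr in cands:                     # ascending: ties keep the lower
        pred = probs > thr
        sens = np.sum(pred & (y == 1)) / npos
        spec = np.sum(~pred & (y == 0)) / nneg
        d = np.hypot(1.0 - sens, 1.0 - spec)
        if d < best_d - 1e-15:
            best_d, best_thr = d, float(thr)
    return best_thr


def clopper_pearson(k: int, n: int, alpha: float = 0.05
                    ) -> tuple[float, float]:
    """Exact binomial (Clopper-Pearson) confidence interval, as proportions.

    lower = BetaInv(alpha/2; k, n-k+1) (0 when k = 0) and
    upper = BetaInv(1-alpha/2; k+1, n-k) (1 when k = n).
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0 <= k <= n:
        raise ValueError("k must lie in [0, n]")
    lo = 0.0 if k == 0 else float(stats.beta.ppf(alpha / 2, k, n - k + 1))
    hi = 1.0 if k == n else float(stats.beta.ppf(1 - alpha / 2, k + 1, n - k))
    return lo, hi


@dataclass
class PerformanceReport:
    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: float            # percentages
    specificity: float
    accuracy: float
    precision: float
    f1: float
    ci: dict                      # metric -> (lower %, upper %)
    threshold: float


def f1_score_pct(precision_pct: float, sensitivity_pct: float) -> float:
    """Harmonic mean of precision and sensitivity, in percent."""
    if np.isnan(precision_pct) or np.isnan(sensitivity_pct):
        return float("nan")
    if precision_pct + sensitivity_pct == 0:
        return 0.0
    return 2.0 * precision_pct * sensitivity_pct / (
        precision_pct + sensitivity_pct)


def performance_metrics(probs: np.ndarray, y: np.ndarray,
                        threshold: float = 0.5,
                        alpha: float = 0.05) -> PerformanceReport:
    """Confusion counts and percentage metrics with exact binomial CIs.

    A subject is predicted positive when its probability exceeds the
    threshold.  Precision and F1 are missing (logged) when nothing is
    predicted positive; CIs are reported for the proportion-type metrics
    (sensitivity, specificity, accuracy, precision) on their respective
    denominators.
    """
    probs = np.asarray(probs, dtype=float)
    y = np.asarray(y, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    pred = probs > threshold
    tp = int(np.sum(pred & (y == 1)))
    fp = int(np.sum(pred & (y == 0)))
    tn = int(np.sum(~pred & (y == 0)))
    fn = int(np.sum(~pred & (y == 1)))

    def pct(k, n):
        return 100.0 * k / n if n > 0 else float("nan")

    sens = pct(tp, tp + fn)
    spec = pct(tn, tn + fp)
    acc = pct(tp + tn, len(y))
    if tp + fp == 0:
        logger.warning("no predicted positives at threshold %.3f", threshold)
        prec = float("nan")
    else:
        prec = pct(tp, tp + fp)
    f1 = f1_score_pct(prec, sens)

    ci = {}
    for metric, (k, n) in {
        "sensitivity": (tp, tp + fn),
        "specificity": (tn, tn + fp),
        "accuracy": (tp + tn, len(y)),
        "precision": (tp, tp + fp),
    }.items():
        if n > 0:
            lo, hi = clopper_pearson(k, n, alpha)
            ci[metric] = (100.0 * lo, 100.0 * hi)
        else:
            ci[metric] = (float("nan"), float("nan"))
    return PerformanceReport(tp=tp, fp=fp, tn=tn, fn=fn,
                             sensitivity=sens, specificity=spec,
                             accuracy=acc, precision=prec, f1=f1,
                             ci=ci, threshold=float(threshold))


def feature_importance(result: ClassificationResult) -> pd.DataFrame:
    """Mean absolute standardized coefficient per feature across folds.

    Folds in which a feature was not selected contribute zero; the table
    is sorted by descending importance.
    """
    n_folds = len(result.fold_features)
    totals: dict[str, float] = {}
    for feats, coefs in zip(result.fold_features, result.fold_coefs):
        for name, c in zip(feats, coefs):
            totals[name] = totals.get(name, 0.0) + abs(float(c))
    rows = [{"feature": name, "importance": tot / n_folds,
             "n_folds_selected": sum(name in f for f in result.fold_features)}
            for name, tot in totals.items()]
    df = pd.DataFrame(rows, columns=["feature", "importance",
                                     "n_folds_selected"])
    return df.sort_values("importance", ascending=False,
                          kind="stable").reset_index(drop=True)


# ---------------------------------------------------------------------------
# Feature-table preparation
# ---------------------------------------------------------------------------

def prepare_matrix(features: pd.DataFrame, task: TaskDefinition,
                   registry_columns: Sequence[str] | None = None,
                   ) -> tuple[np.ndarray, np.ndarray, list[str], list[str]]:
    """(X, y, feature_names, subject_ids) for one task from a feature table.

    Subjects outside the task's classes or with any missing feature row
    (e.g. a single valid day, hence missing variances) are dropped;
    feature columns that are missing or constant for the remaining
    subjects are dropped as uninformative.
    """
    if registry_columns is None:
        meta = {"subject_id", "diagnosis", "age", "sex", "antidepressant",
                "antipsychotic", "hypnotic", "sedative_analgesic", "mmse"}
        registry_columns = [c for c in features.columns if c not in meta]
    y_all, include = task.labels(features["diagnosis"].to_numpy())
    sub = features.loc[include].reset_index(drop=True)
    X = sub[list(registry_columns)].to_numpy(dtype=float)
    row_ok = ~np.isnan(X).all(axis=1)
    # subjects with missing variance block (one valid day) are dropped
    col_any_nan = np.isnan(X).any(axis=0)
    row_has_nan = np.isnan(X[:, ~col_any_nan]).any(axis=1) if (~col_any_nan).any() else np.zeros(len(X), bool)
    keep_rows = row_ok & ~row_has_nan
    X = X[keep_rows]
    y = y_all[keep_rows]
    sids = sub.loc[keep_rows, "subject_id"].astype(str).tolist()
    col_keep = ~np.isnan(X).any(axis=0)
    col_keep &= X.std(axis=0) > 0
    names = [c for c, k in zip(registry_columns, col_keep) if k]
    return X[:, col_keep], y, names, sids
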