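"""Logistic models and the small-sample validation battery.

Fitting is plain maximum likelihood (iteratively reweighted least squares);
discrimination is summarized by the Mann-Whitney AUC with a stratified
percentile-bootstrap CI; model comparison uses the paired DeLong test;
operating points come from the Youden index with Jeffreys (Beta(x+1/2,
n-x+1/2)) intervals for the classification metrics; internal validation is
a repeated stratified k-fold CV and, for the progression models, a
bootstrap "average model" whose coefficients are the mean over refits on
resampled cohorts.

Throughout, a case is called positive when its predicted probability (or
score) is at or above the threshold, and "sensitivity" refers to the
positive class (late CKD at baseline; rapid progressor for the slope
endpoint).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "FittedModel",
    "fit_logistic",
    "calibration_test",
    "roc_auc",
    "auc_ci_bootstrap",
    "delong_compare",
    "youden_threshold",
    "jeffreys_ci",
    "classification_report",
    "repeated_cv",
    "bootstrap_average_model",
    "SeparationWarning",
]

#: |standardized coefficient| beyond which the fit is flagged as separated
SEPARATION_BOUND = 15.0
_MAX_ITER = 100
_TOL = 1e-8


class SeparationWarning(UserWarning):
    pass


@dataclass
class FittedModel:
    """A fitted logistic regression on the original covariate scale."""

    feature_names: list[str]
    intercept: float
    coefficients: np.ndarray
    converged: bool
    separation: bool
    log_likelihood: float
    n_iter: int

    def linear_predictor(self, X) -> np.ndarray:
        X = _as_matrix(X, self.feature_names)
        return self.intercept + X @ self.coefficients

    def predict_proba(self, X) -> np.ndarray:
        return _sigmoid(self.linear_predictor(X))


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(z, -700, 700)))


def _as_matrix(X, names: list[str] | None = None) -> np.ndarray:
    if isinstance(X, pd.DataFrame):
        if names is not None:
            X = X[names]
        return X.to_numpy(dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    return X


def _log_likelihood(y: np.ndarray, p: np.ndarray) -> float:
    p = np.clip(p, 1e-12, 1 - 1e-12)
    return float(np.sum(y * np.log(p) + (1 - y) * np.log(1 - p)))


def fit_logistic(X, y) -> FittedModel:
    """Maximum-likelihood logistic regression via IRLS.

    Covariates are standardized internally for numerical stability and for
    separation detection: a standardized coefficient exceeding 15 in
    absolute value flags complete/quasi-separation, the coefficients are
    capped there, and downstream metrics are still computed from the
    capped fit. Rank-deficient designs raise an error naming the collinear
    columns.
    """
    names = list(X.columns) if isinstance(X, pd.DataFrame) else [f"x{i}" for i in range(np.atleast_2d(X).shape[-1] if np.asarray(X).ndim > 1 else 1)]
    Xm = _as_matrix(X)
    y = np.asarray(y, dtype=float).ravel()
    if len(np.unique(y)) < 2:
        raise ValueError("outcome has a single class; cannot fit")
    if np.isnan(Xm).any() or np.isnan(y).any():
        raise ValueError("missing values in the design or outcome")

    mean = Xm.mean(axis=0)
    sd = Xm.std(axis=0, ddof=0)
    degenerate = [names[j] for j in range(Xm.shape[1]) if sd[j] == 0]
    if degenerate:
        raise ValueError(f"collinear (constant) columns: {degenerate}")
    Z = (Xm - mean) / sd
    design = np.column_stack([np.ones(len(y)), Z])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        collinear = []
        for j in range(Z.shape[1]):
            reduced = np.delete(design, j + 1, axis=1)
            if np.linalg.matrix_rank(reduced) == rank:
                collinear.append(names[j])
        raise ValueError(f"rank-deficient design; collinear columns: {collinear}")

    def _irls(ridge: float, max_iter: int = _MAX_ITER):
        beta = np.zeros(design.shape[1])
        pen = ridge * np.eye(design.shape[1])
        pen[0, 0] = 0.0  # intercept unpenalized
        for it in range(1, max_iter + 1):
            p = _sigmoid(design @ beta)
            w = np.clip(p * (1 - p), 1e-10, None)
            H = design.T @ (design * w[:, None]) + pen
            grad = design.T @ (y - p) - pen @ beta
            try:
                step = np.linalg.solve(H, grad)
            except np.linalg.LinAlgError:
                step = np.linalg.solve(H + 1e-8 * np.eye(len(beta)), grad)
            beta = beta + step
            if np.max(np.abs(step)) < _TOL:
                return beta, True, it
            if np.max(np.abs(beta)) > 10 * SEPARATION_BOUND:
                return beta, False, it  # diverging towards separation
        return beta, False, max_iter

    beta, converged, it = _irls(0.0)
    separation = (not converged and it < _MAX_ITER) or bool(
        np.any(np.abs(beta) > SEPARATION_BOUND)
    )
    if separation:
        # capped fit: a lightly ridged refit gives a stable direction, the
        # slope vector is scaled so its largest standardized coefficient
        # sits at the bound, and the intercept is re-optimized for the
        # fixed slopes
        beta, _, _ = _irls(1e-2, max_iter=200)
        m = np.max(np.abs(beta[1:]))
        if m > SEPARATION_BOUND:
            beta[1:] *= SEPARATION_BOUND / m
        offset = Z @ beta[1:]
        b0 = beta[0]
        for _ in range(50):
            p = _sigmoid(b0 + offset)
            denom = max(np.sum(p * (1 - p)), 1e-10)
            step = np.sum(y - p) / denom
            b0 += step
            if abs(step) < _TOL:
                break
        beta[0] = float(np.clip(b0, -SEPARATION_BOUND, SEPARATION_BOUND))

    coef = beta[1:] / sd
    intercept = float(beta[0] - np.sum(beta[1:] * mean / sd))
    ll = _log_likelihood(y, _sigmoid(design @ beta))
    return FittedModel(
        feature_names=names,
        intercept=intercept,
        coefficients=coef,
        converged=converged and not separation,
        separation=separation,
        log_likelihood=ll,
        n_iter=it,
    )


def calibration_test(model: FittedModel, X, y) -> float:
    """Likelihood-based calibration p-value (recalibration test).

    The outcome is refitted on the model's linear predictor with a free
    intercept and slope; twice the log-likelihood gain over the fixed
    (0, 1) recalibration is referred to a chi-square with 2 df. A model
    evaluated on its own training data gives statistic 0, p = 1. Returns
    NaN when the predictions are degenerate (all equal).
    """
    y = np.asarray(y, dtype=float).ravel()
    lp = model.linear_predictor(X)
    if np.ptp(lp) == 0:
        return float("nan")
    ll_fixed = _log_likelihood(y, _sigmoid(lp))
    recal = fit_logistic(pd.DataFrame({"lp": lp}), y)
    stat = max(0.0, 2.0 * (recal.log_likelihood - ll_fixed))
    return float(stats.chi2.sf(stat, df=2))


def roc_auc(scores, labels) -> float:
    """Mann-Whitney AUC: P(score_pos > score_neg) + 1/2 P(tie)."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int)
    n1 = int(y.sum())
    n0 = len(y) - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes required")
    ranks = stats.rankdata(s)
    u = ranks[y == 1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def _auc_rows(pos: np.ndarray, neg: np.ndarray) -> np.ndarray:
    """Row-wise Mann-Whitney AUC for matrices of resampled scores."""
    comb = np.concatenate([pos, neg], axis=1)
    ranks = stats.rankdata(comb, axis=1)
    n1 = pos.shape[1]
    n0 = neg.shape[1]
    u = ranks[:, :n1].sum(axis=1) - n1 * (n1 + 1) / 2.0
    return u / (n1 * n0)


def auc_ci_bootstrap(
    scores, labels, B: int = 2000, seed: int | None = None, level: float = 0.95
) -> tuple[float, float]:
    """Stratified percentile-bootstrap CI for the AUC.

    Positives and negatives are resampled separately with replacement,
    preserving the class counts; the interval is the (2.5, 97.5) percentile
    of the B resampled AUCs (for level 0.95).
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int)
    pos = s[y == 1]
    neg = s[y == 0]
    if len(pos) < 2 or len(neg) < 2:
        raise ValueError("each class needs at least two cases to resample")
    rng = np.random.default_rng(seed)
    pos_rs = pos[rng.integers(0, len(pos), size=(B, len(pos)))]
    neg_rs = neg[rng.integers(0, len(neg), size=(B, len(neg)))]
    aucs = _auc_rows(pos_rs, neg_rs)
    alpha = (1.0 - level) / 2.0
    lo, hi = np.percentile(aucs, [100 * alpha, 100 * (1 - alpha)])
    return float(lo), float(hi)


def _midrank(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def _delong_placements(scores: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    """AUC and the per-case placement values of one score vector."""
    pos = scores[y == 1]
    neg = scores[y == 0]
    m, n = len(pos), len(neg)
    tx = _midrank(pos)
    ty = _midrank(neg)
    tz = _midrank(np.concatenate([pos, neg]))
    auc = (tz[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    v10 = (tz[:m] - tx) / n  # per-positive placements
    v01 = 1.0 - (tz[m:] - ty) / m  # per-negative placements
    return float(auc), v10, v01


def delong_compare(scores_a, scores_b, labels) -> tuple[float, float, float]:
    """Paired DeLong comparison of two AUCs on the same patients.

    Returns (AUC_a - AUC_b, z, two-sided p). Identical score rankings give
    zero variance of the difference; that case is reported as p = 1.
    """
    y = np.asarray(labels).astype(int)
    sa = np.asarray(scores_a, dtype=float)
    sb = np.asarray(scores_b, dtype=float)
    if len(sa) != len(sb) or len(sa) != len(y):
        raise ValueError("paired scores must align with the labels")
    auc_a, v10_a, v01_a = _delong_placements(sa, y)
    auc_b, v10_b, v01_b = _delong_placements(sb, y)
    m, n = len(v10_a), len(v01_a)
    s10 = np.cov(np.vstack([v10_a, v10_b]), ddof=1)
    s01 = np.cov(np.vstack([v01_a, v01_b]), ddof=1)
    cov = s10 / m + s01 / n
    var = cov[0, 0] + cov[1, 1] - 2.0 * cov[0, 1]
    dauc = auc_a - auc_b
    if var <= 0:
        return float(dauc), 0.0, 1.0
    z = dauc / np.sqrt(var)
    p = 2.0 * stats.norm.sf(abs(z))
    return float(dauc), float(z), float(min(p, 1.0))


def youden_threshold(scores, labels) -> tuple[float, float]:
    """Threshold maximizing Youden's J = sensitivity + specificity - 1.

    Candidates are the observed score values under the rule "positive iff
    score >= threshold"; ties are broken toward the lowest threshold
    (favouring sensitivity). Returns (threshold, J).
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int)
    pos = s[y == 1]
    neg = s[y == 0]
    best_t, best_j = None, -np.inf
    for t in np.sort(np.unique(s)):
        sens = float(np.mean(pos >= t))
        spec = float(np.mean(neg < t))
        j = sens + spec - 1.0
        if j > best_j + 1e-12:
            best_j, best_t = j, float(t)
    return best_t, float(best_j)


def jeffreys_ci(successes: int, trials: int, level: float = 0.95) -> tuple[float, float]:
    """Jeffreys interval for a binomial proportion.

    Quantiles of Beta(x + 1/2, n - x + 1/2), with the conventional
    boundary values: lower limit 0 when x = 0, upper limit 1 when x = n.
    """
    if not 0 <= successes <= trials or trials < 1:
        raise ValueError("need 0 <= successes <= trials, trials >= 1")
    alpha = (1.0 - level) / 2.0
    lo = 0.0 if successes == 0 else float(stats.beta.ppf(alpha, successes + 0.5, trials - successes + 0.5))
    hi = 1.0 if successes == trials else float(stats.beta.ppf(1 - alpha, successes + 0.5, trials - successes + 0.5))
    return lo, hi


def classification_report(scores, labels, threshold: float) -> dict:
    """Accuracy, sensitivity and specificity (with Jeffreys 95% CIs) at a
    probability threshold, plus the confusion counts."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int)
    pred = (s >= threshold).astype(int)
    tp = int(((pred == 1) & (y == 1)).sum())
    fn = int(((pred == 0) & (y == 1)).sum())
    tn = int(((pred == 0) & (y == 0)).sum())
    fp = int(((pred == 1) & (y == 0)).sum())
    n = len(y)
    n_pos, n_neg = tp + fn, tn + fp
    return {
        "threshold": float(threshold),
        "counts": {"tp": tp, "fn": fn, "tn": tn, "fp": fp},
        "accuracy": (tp + tn) / n,
        "accuracy_ci": jeffreys_ci(tp + tn, n),
        "sensitivity": tp / n_pos if n_pos else float("nan"),
        "sensitivity_ci": jeffreys_ci(tp, n_pos) if n_pos else (float("nan"),) * 2,
        "specificity": tn / n_neg if n_neg else float("nan"),
        "specificity_ci": jeffreys_ci(tn, n_neg) if n_neg else (float("nan"),) * 2,
    }


def _stratified_folds(y: np.ndarray, k: int, rng: np.random.Generator) -> list[np.ndarray]:
    """Index sets of k folds with class proportions balanced within one."""
    folds: list[list[int]] = [[] for _ in range(k)]
    counter = 0  # global round-robin keeps total fold sizes within one
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        rng.shuffle(idx)
        for ix in idx:
            folds[counter % k].append(int(ix))
            counter += 1
    return [np.sort(np.array(f)) for f in folds]


def repeated_cv(
    X,
    y,
    k: int = 3,
    repeats: int = 5,
    seed: int | None = None,
) -> dict:
    """Repeated stratified k-fold cross-validation of a logistic model.

    Per fold the model is fitted on the training part and its Youden
    threshold is taken from the training predictions; test-set predictions
    of the k folds of one repetition are pooled before computing AUC,
    accuracy, sensitivity and specificity. The summary is the mean and SD
    of each metric over the repetitions.
    """
    Xdf = X if isinstance(X, pd.DataFrame) else pd.DataFrame(_as_matrix(X))
    y = np.asarray(y).astype(int)
    counts = np.bincount(y)
    if counts.min() < k:
        raise ValueError(f"smallest class ({counts.min()}) cannot fill {k} folds")
    rng = np.random.default_rng(seed)
    per_rep = {"auc": [], "accuracy": [], "sensitivity": [], "specificity": []}
    fold_log = []
    for rep in range(repeats):
        folds = _stratified_folds(y, k, rng)
        test_scores = np.empty(len(y))
        test_pred = np.empty(len(y), dtype=int)
        for fi, test_idx in enumerate(folds):
            train_idx = np.setdiff1d(np.arange(len(y)), test_idx)
            model = fit_logistic(Xdf.iloc[train_idx], y[train_idx])
            thr, _ = youden_threshold(model.predict_proba(Xdf.iloc[train_idx]), y[train_idx])
            sc = model.predict_proba(Xdf.iloc[test_idx])
            test_scores[test_idx] = sc
            test_pred[test_idx] = (sc >= thr).astype(int)
            fold_log.append({"repetition": rep, "fold": fi, "threshold": thr, "n_test": len(test_idx)})
        per_rep["auc"].append(roc_auc(test_scores, y))
        tp = int(((test_pred == 1) & (y == 1)).sum())
        tn = int(((test_pred == 0) & (y == 0)).sum())
        per_rep["accuracy"].append((tp + tn) / len(y))
        per_rep["sensitivity"].append(tp / int((y == 1).sum()))
        per_rep["specificity"].append(tn / int((y == 0).sum()))
    summary = {
        m: {"mean": float(np.mean(v)), "sd": float(np.std(v, ddof=1)), "values": [float(x) for x in v]}
        for m, v in per_rep.items()
    }
    summary["folds"] = fold_log
    summary["k"] = k
    summary["repeats"] = repeats
    return summary


def bootstrap_average_model(
    X,
    y,
    B: int = 1000,
    seed: int | None = None,
) -> tuple[FittedModel, dict]:
    """Internal validation by a bootstrap "average model".

    The cohort is resampled B times with class-stratified resampling, a
    logistic model is refitted on each replicate, separation-flagged
    replicates are excluded (and counted), and the remaining coefficient
    vectors are averaged arithmetically. The averaged model is then
    evaluated on the full cohort (AUC, Youden threshold and classification
    metrics).
    """
    Xdf = X if isinstance(X, pd.DataFrame) else pd.DataFrame(_as_matrix(X))
    y = np.asarray(y).astype(int)
    rng = np.random.default_rng(seed)
    pos_idx = np.flatnonzero(y == 1)
    neg_idx = np.flatnonzero(y == 0)
    intercepts, coefs = [], []
    n_excluded = 0
    for _ in range(B):
        idx = np.concatenate(
            [
                pos_idx[rng.integers(0, len(pos_idx), len(pos_idx))],
                neg_idx[rng.integers(0, len(neg_idx), len(neg_idx))],
            ]
        )
        try:
            m = fit_logistic(Xdf.iloc[idx], y[idx])
        except ValueError:
            n_excluded += 1
            continue
        if m.separation:
            n_excluded += 1
            continue
        intercepts.append(m.intercept)
        coefs.append(m.coefficients)
    if not intercepts:
        raise ValueError("every bootstrap replicate was excluded")
    avg = FittedModel(
        feature_names=list(Xdf.columns),
        intercept=float(np.mean(intercepts)),
        coefficients=np.mean(coefs, axis=0),
        converged=True,
        separation=False,
        log_likelihood=float("nan"),
        n_iter=0,
    )
    scores = avg.predict_proba(Xdf)
    thr, j = youden_threshold(scores, y)
    metrics = classification_report(scores, y, thr)
    metrics.update(
        {
            "auc": roc_auc(scores, y),
            "youden_j": j,
            "n_replicates": B,
            "n_excluded": n_excluded,
            "n_used": len(intercepts),
        }
    )
    return avg, metrics
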