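"""Regression and binary-classification metrics for ΔΔG benchmarking.

Regression: Pearson / Spearman / Kendall tau-b correlations plus RMSE and
MAE between predicted and experimental folding free-energy changes.

Classification: confusion counts at a threshold (predicted positive iff
``score > threshold``, strictly — the single convention used throughout
the package, matching the strict ``ΔΔG > 2`` destabilization label),
accuracy (percent), Matthews correlation coefficient, ROC AUC, and
threshold selection by balancing the true-positive and true-negative
rates, optionally inside a stratified cross-validation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.metrics import roc_auc_score

from .variant_table import exclude_variants as exclude_outliers  # noqa: F401

__all__ = [
    "RegressionMetrics",
    "ClassificationMetrics",
    "ThresholdSearchResult",
    "regression_metrics",
    "confusion_at",
    "auc",
    "optimize_threshold",
    "cv_threshold",
    "exclude_outliers",
]


@dataclass(frozen=True)
class RegressionMetrics:
    """Correlation/error summary of predicted vs experimental values.

    Correlations are dimensionless in [-1, 1] (NaN when undefined, e.g.
    zero-variance input); rmse and mae are in kcal/mol, with
    ``rmse >= mae`` always.
    """

    pearson_r: float
    spearman_rho: float
    kendall_tau: float
    rmse: float
    mae: float
    n: int


@dataclass(frozen=True)
class ClassificationMetrics:
    """Confusion counts and derived scores at a fixed threshold.

    ``accuracy`` is a percentage; ``mcc`` is 0 by convention when any
    marginal of the confusion table is 0; ``auc`` is threshold-free (NaN
    when only one class is present); ``tpr``/``tnr`` are fractions (NaN
    for an empty class).
    """

    threshold: float
    tp: int
    fp: int
    tn: int
    fn: int
    accuracy: float
    mcc: float
    auc: float
    tpr: float
    tnr: float


@dataclass(frozen=True)
class ThresholdSearchResult:
    """Outcome of balanced-rate threshold selection.

    ``criterion_value`` is |tpr - tnr| at the selected threshold on the
    data it was selected from; ``fold_thresholds`` is populated when the
    threshold is the median over cross-validation folds.
    """

    threshold: float
    criterion_value: float
    fold_thresholds: tuple[float, ...] = ()
    seed: int | None = None


def regression_metrics(pred, obs) -> RegressionMetrics:
    """Correlations and errors between paired predictions and observations.

    Pearson is the product-moment correlation, Spearman the rank
    correlation, Kendall the tie-corrected tau-b.  ``rmse`` is
    sqrt(mean squared error), ``mae`` the mean absolute error.  With
    zero-variance input the correlations are undefined and reported as
    NaN with a warning.
    """
    pred = np.asarray(pred, dtype=float)
    obs = np.asarray(obs, dtype=float)
    if pred.shape != obs.shape:
        raise ValueError("pred and obs must have equal length")
    n = pred.size
    if n < 2:
        raise ValueError(f"need at least 2 paired values, got {n}")
    err = pred - obs
    rmse = float(np.sqrt(np.mean(err**2)))
    mae = float(np.mean(np.abs(err)))
    if np.ptp(pred) == 0 or np.ptp(obs) == 0:
        warnings.warn("zero-variance input: correlations undefined", stacklevel=2)
        r = rho = tau = float("nan")
    else:
        r = float(stats.pearsonr(pred, obs).statistic)
        rho = float(stats.spearmanr(pred, obs).statistic)
        tau = float(stats.kendalltau(pred, obs).statistic)  # tau-b
    return RegressionMetrics(r, rho, tau, rmse, mae, n)


def _mcc(tp: int, fp: int, tn: int, fn: int) -> float:
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return 0.0
    return (tp * tn - fp * fn) / np.sqrt(denom)


def confusion_at(scores, labels, threshold: float) -> ClassificationMetrics:
    """All classification metrics at one threshold (positive iff score > t)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if scores.size == 0:
        raise ValueError("empty input")
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have equal length")
    pred = scores > threshold
    tp = int(np.sum(pred & labels))
    fp = int(np.sum(pred & ~labels))
    tn = int(np.sum(~pred & ~labels))
    fn = int(np.sum(~pred & labels))
    total = tp + fp + tn + fn
    accuracy = 100.0 * (tp + tn) / total
    npos, nneg = tp + fn, tn + fp
    tpr = tp / npos if npos else float("nan")
    tnr = tn / nneg if nneg else float("nan")
    auc_val = auc(scores, labels) if (npos and nneg) else float("nan")
    return ClassificationMetrics(
        threshold=float(threshold), tp=tp, fp=fp, tn=tn, fn=fn,
        accuracy=accuracy, mcc=float(_mcc(tp, fp, tn, fn)),
        auc=auc_val, tpr=tpr, tnr=tnr)


def auc(scores, labels) -> float:
    """Area under the ROC curve.

    Equals the Mann–Whitney probability that a random positive outscores
    a random negative, with ties counting one half.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if labels.all() or not labels.any():
        raise ValueError("AUC requires at least one positive and one negative")
    return float(roc_auc_score(labels, scores))


def threshold_candidates(scores) -> np.ndarray:
    """Candidate thresholds for the balanced-rate scan.

    Midpoints between consecutive sorted unique scores, plus one candidate
    below the minimum (everything predicted positive) and one at the
    maximum (everything predicted negative, since the decision rule is
    strict ``>``).
    """
    uniq = np.unique(np.asarray(scores, dtype=float))
    if uniq.size == 1:
        step = 1.0
    else:
        step = float(np.mean(np.diff(uniq)))
    mids = (uniq[:-1] + uniq[1:]) / 2.0
    return np.concatenate(([uniq[0] - step / 2.0], mids, [uniq[-1]]))


def optimize_threshold(scores, labels) -> ThresholdSearchResult:
    """Select the threshold balancing sensitivity and specificity.

    Scans all candidates from :func:`threshold_candidates` and returns the
    one minimizing |tpr - tnr|; ties are broken by larger MCC, then by
    smaller threshold.  Deterministic and independent of input order.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if labels.all() or not labels.any():
        raise ValueError("threshold optimization requires both classes")
    best: tuple[float, float, float] | None = None  # (|tpr-tnr|, -mcc, t)
    for t in threshold_candidates(scores):
        m = confusion_at(scores, labels, t)
        key = (abs(m.tpr - m.tnr), -m.mcc, t)
        if best is None or key < best:
            best = key
    assert best is not None
    return ThresholdSearchResult(threshold=float(best[2]),
                                 criterion_value=float(best[0]))


def cv_threshold(scores, labels, k: int = 5, seed: int = 0) -> ThresholdSearchResult:
    """Balanced-rate threshold selected by stratified k-fold cross-validation.

    For each fold the threshold is optimized on the k-1 training folds;
    the final threshold is the median of the fold thresholds.  The fold
    assignment is seeded and stratified so every training split contains
    both classes.
    """
    from sklearn.model_selection import StratifiedKFold

    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if scores.size < k:
        raise ValueError(f"need at least k={k} samples, got {scores.size}")
    n_min = int(min(labels.sum(), (~labels).sum()))
    if n_min < k:
        raise ValueError(
            f"minority class has {n_min} members; use k <= {n_min} folds")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    fold_ts = []
    for train_idx, _ in skf.split(scores.reshape(-1, 1), labels):
        fold_ts.append(optimize_threshold(scores[train_idx], labels[train_idx]).threshold)
    t = float(np.median(fold_ts))
    m = confusion_at(scores, labels, t)
    return ThresholdSearchResult(threshold=t,
                                 criterion_value=float(abs(m.tpr - m.tnr)),
                                 fold_thresholds=tuple(fold_ts), seed=seed)
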