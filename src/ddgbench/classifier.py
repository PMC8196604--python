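"""Scikit-learn estimator turning a continuous score into a binary classifier.

A stability predictor (ΔΔG in kcal/mol) or pathogenicity score in [0, 1]
becomes a classifier by choosing a cut-off.  :class:`ThresholdClassifier`
selects the cut-off that balances sensitivity and specificity
(minimizing |TPR − TNR|), optionally via stratified cross-validation, or
applies a fixed, externally chosen threshold.  It composes with sklearn
pipelines and model selection.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from . import metrics as _metrics


class ThresholdClassifier(ClassifierMixin, BaseEstimator):
    """Binary classifier from a single continuous score.

    Parameters
    ----------
    threshold : float, optional
        Fixed decision threshold.  When given, ``fit`` only validates the
        data and stores it; no search is run.
    cv : int, optional
        Number of stratified folds for cross-validated threshold
        selection.  ``None`` (default) optimizes on the full training data.
    random_state : int, default 0
        Seed for the fold shuffle when ``cv`` is set.

    Attributes
    ----------
    threshold_ : float
        Selected (or fixed) decision threshold.
    fold_thresholds_ : tuple of float
        Per-fold thresholds when ``cv`` was used, else empty.
    criterion_value_ : float
        |TPR − TNR| on the training data at ``threshold_``.
    classes_ : ndarray
        Always ``[False, True]``.

    The decision rule is strict: predicted positive iff
    ``score > threshold_``.
    """

    def __init__(self, threshold: float | None = None, cv: int | None = None,
                 random_state: int = 0):
        self.threshold = threshold
        self.cv = cv
        self.random_state = random_state

    @staticmethod
    def _scores(X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 2:
            if X.shape[1] != 1:
                raise ValueError("ThresholdClassifier expects a single score column")
            X = X[:, 0]
        elif X.ndim != 1:
            raise ValueError("X must be 1-D scores or a (n, 1) column")
        if np.isnan(X).any():
            raise ValueError("scores contain NaN")
        return X

    def fit(self, X, y):
        s = self._scores(X)
        y = np.asarray(y, dtype=bool)
        if s.shape != y.shape:
            raise ValueError("X and y length mismatch")
        if self.threshold is not None:
            self.threshold_ = float(self.threshold)
            self.fold_thresholds_ = ()
            m = _metrics.confusion_at(s, y, self.threshold_)
            self.criterion_value_ = float(abs(m.tpr - m.tnr))
        elif self.cv is not None:
            res = _metrics.cv_threshold(s, y, k=self.cv, seed=self.random_state)
            self.threshold_ = res.threshold
            self.fold_thresholds_ = res.fold_thresholds
            self.criterion_value_ = res.criterion_value
        else:
            res = _metrics.optimize_threshold(s, y)
            self.threshold_ = res.threshold
            self.fold_thresholds_ = ()
            self.criterion_value_ = res.criterion_value
        self.classes_ = np.array([False, True])
        self.n_features_in_ = 1
        return self

    def decision_function(self, X) -> np.ndarray:
        check_is_fitted(self, "threshold_")
        return self._scores(X) - self.threshold_

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "threshold_")
        return self._scores(X) > self.threshold_

    def evaluate(self, X, y) -> "_metrics.ClassificationMetrics":
        """Full confusion-matrix metrics of this classifier on (X, y)."""
        check_is_fitted(self, "threshold_")
        return _metrics.confusion_at(self._scores(X), np.asarray(y, dtype=bool),
                                     self.threshold_)
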