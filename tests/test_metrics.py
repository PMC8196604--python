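import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ddgbench.metrics import (
    auc,
    confusion_at,
    cv_threshold,
    optimize_threshold,
    regression_metrics,
    threshold_candidates,
)


def _pearson_oracle(x, y):
    """Product-moment formula, written out independently of scipy."""
    n = len(x)
    mx, my = sum(x) / n, sum(y) / n
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sxx = sum((a - mx) ** 2 for a in x)
    syy = sum((b - my) ** 2 for b in y)
    return sxy / math.sqrt(sxx * syy)


class TestRegressionMetrics:
    def test_identity_input(self):
        m = regression_metrics([1, 2, 3], [1, 2, 3])
        assert m.pearson_r == pytest.approx(1.0)
        assert m.rmse == 0.0 and m.mae == 0.0 and m.n == 3

    def test_against_formula_oracle(self):
        pred, obs = [0.0, 1.0, 2.0, 4.0], [0.0, 1.0, 2.0, 2.0]
        m = regression_metrics(pred, obs)
        assert m.pearson_r == pytest.approx(_pearson_oracle(pred, obs))
        # errors: only the last pair differs, by 2
        assert m.mae == pytest.approx(2.0 / 4.0)
        assert m.rmse == pytest.approx(math.sqrt(4.0 / 4.0))
        assert m.rmse >= m.mae

    def test_affine_transform_gives_exact_unit_pearson(self, rng):
        x = rng.normal(size=40)
        m = regression_metrics(x, 2.5 * x - 1.0)
        assert m.pearson_r == pytest.approx(1.0, abs=1e-12)

    def test_zero_variance_reports_nan_with_warning(self):
        with pytest.warns(UserWarning, match="zero-variance"):
            m = regression_metrics([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        assert math.isnan(m.pearson_r)
        assert m.rmse > 0  # errors remain defined

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            regression_metrics([1.0], [1.0])

    @given(st.lists(st.tuples(st.floats(-50, 50), st.floats(-50, 50)),
                    min_size=2, max_size=60))
    @settings(deadline=None, max_examples=60)
    def test_rmse_dominates_mae(self, pairs):
        import warnings

        pred, obs = zip(*pairs)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # zero-variance columns are fine here
            m = regression_metrics(list(pred), list(obs))
        assert m.rmse >= m.mae - 1e-12


class TestConfusionAt:
    def test_perfect_separation(self):
        m = confusion_at([0, 0.1, 0.9, 1.0], [False, False, True, True], 0.5)
        assert m.accuracy == 100.0 and m.mcc == pytest.approx(1.0)

    def test_known_counts_match_formula(self):
        # scores/labels realizing (tp, fp, fn, tn) = (3, 1, 1, 5) at t=0.5
        scores = [0.9] * 3 + [0.9] + [0.1] + [0.1] * 5
        labels = [True] * 3 + [False] + [True] + [False] * 5
        m = confusion_at(scores, labels, 0.5)
        assert (m.tp, m.fp, m.fn, m.tn) == (3, 1, 1, 5)
        assert m.accuracy == pytest.approx(80.0)
        assert m.mcc == pytest.approx(14.0 / 24.0)

    def test_strict_inequality_at_threshold(self):
        m = confusion_at([2.0], [True], 2.0)
        assert m.fn == 1 and m.tp == 0  # score == threshold -> negative

    def test_degenerate_marginal_gives_zero_mcc(self):
        m = confusion_at([1.0, 2.0], [True, True], 0.0)
        assert m.mcc == 0.0
        assert math.isnan(m.tnr)

    def test_empty_input_errors(self):
        with pytest.raises(ValueError):
            confusion_at([], [], 0.0)


def _auc_pair_count(scores, labels):
    pos = [s for s, l in zip(scores, labels) if l]
    neg = [s for s, l in zip(scores, labels) if not l]
    wins = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
    return wins / (len(pos) * len(neg))


class TestAuc:
    def test_examples(self):
        assert auc([1, 2, 3, 4], [False, False, True, True]) == 1.0
        assert auc([1, 3, 2, 4], [False, False, True, True]) == 0.75
        assert auc([5, 5, 5, 5], [False, True, False, True]) == 0.5

    def test_single_class_errors(self):
        with pytest.raises(ValueError):
            auc([1, 2], [True, True])

    @given(st.integers(0, 2**32 - 1))
    @settings(deadline=None, max_examples=25)
    def test_matches_pair_counting_oracle(self, seed):
        r = np.random.default_rng(seed)
        n = int(r.integers(2, 30))
        scores = r.integers(0, 6, size=n).astype(float)  # many ties
        labels = r.integers(0, 2, size=n).astype(bool)
        if labels.all() or not labels.any():
            return
        assert auc(scores, labels) == pytest.approx(
            _auc_pair_count(scores, labels))

    @given(st.integers(0, 2**32 - 1))
    @settings(deadline=None, max_examples=25)
    def test_invariant_under_monotone_transform(self, seed):
        r = np.random.default_rng(seed)
        scores = r.normal(size=25)
        labels = np.concatenate([np.ones(10, bool), np.zeros(15, bool)])
        base = auc(scores, labels)
        for f in (np.exp, lambda s: s**3, lambda s: 10 * s + 3):
            assert auc(f(scores), labels) == pytest.approx(base)


def _brute_force_threshold(scores, labels):
    """Exhaustive scan over the same candidate set, re-deriving the metrics."""
    best = None
    for t in threshold_candidates(scores):
        pred = np.asarray(scores) > t
        labels = np.asarray(labels, bool)
        tp = int((pred & labels).sum()); fp = int((pred & ~labels).sum())
        tn = int((~pred & ~labels).sum()); fn = int((~pred & labels).sum())
        tpr = tp / max(tp + fn, 1); tnr = tn / max(tn + fp, 1)
        denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
        mcc = (tp * tn - fp * fn) / math.sqrt(denom) if denom else 0.0
        key = (abs(tpr - tnr), -mcc, t)
        if best is None or key < best:
            best = key
    return best[2]


class TestThresholdSelection:
    def test_perfect_separation_returns_gap_midpoint(self):
        res = optimize_threshold([0.0, 1.0, 10.0, 11.0],
                                 [False, False, True, True])
        assert res.threshold == pytest.approx(5.5)
        assert res.criterion_value == 0.0

    def test_matches_brute_force_scan(self, rng):
        for _ in range(20):
            n = int(rng.integers(6, 40))
            scores = np.round(rng.normal(size=n), 1)
            labels = rng.integers(0, 2, size=n).astype(bool)
            if labels.all() or not labels.any():
                continue
            assert optimize_threshold(scores, labels).threshold == pytest.approx(
                _brute_force_threshold(scores, labels))

    def test_order_independent(self, rng):
        scores = rng.normal(size=30)
        labels = rng.integers(0, 2, size=30).astype(bool)
        if labels.all() or not labels.any():
            labels[0] = ~labels[0]
        base = optimize_threshold(scores, labels).threshold
        perm = rng.permutation(30)
        assert optimize_threshold(scores[perm], labels[perm]).threshold == base

    def test_single_class_errors(self):
        with pytest.raises(ValueError):
            optimize_threshold([1, 2, 3], [True, True, True])


class TestCvThreshold:
    def test_reproducible_under_seed(self, rng):
        scores = rng.normal(size=60)
        labels = scores + rng.normal(size=60) > 0
        a = cv_threshold(scores, labels, k=5, seed=7)
        b = cv_threshold(scores, labels, k=5, seed=7)
        assert a == b
        assert len(a.fold_thresholds) == 5 and a.seed == 7

    def test_replicated_data_recovers_full_data_threshold(self):
        scores = np.tile([0.0, 1.0, 10.0, 11.0], 10)
        labels = np.tile([False, False, True, True], 10)
        res = cv_threshold(scores, labels, k=5, seed=0)
        assert res.threshold == pytest.approx(
            optimize_threshold(scores, labels).threshold)

    def test_fold_thresholds_within_per_fold_scan_range(self, rng):
        scores = rng.normal(size=200)
        labels = scores + rng.normal(scale=1.5, size=200) > 0.2
        res = cv_threshold(scores, labels, k=5, seed=3)
        lo, hi = scores.min(), scores.max()
        assert all(lo - 1 <= t <= hi for t in res.fold_thresholds)
        assert lo - 1 <= res.threshold <= hi

    def test_small_minority_class_suggests_smaller_k(self):
        scores = list(range(10))
        labels = [True] * 2 + [False] * 8
        with pytest.raises(ValueError, match="k <="):
            cv_threshold(scores, labels, k=5, seed=0)
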