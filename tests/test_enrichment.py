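import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from ddgbench.enrichment import (
    QuadrantSpec,
    binomial_corner_test,
    burial_fractions,
    class_means,
    fisher_2x2,
    ks_two_sample,
    quadrant_counts,
)

from conftest import make_dataset


def fisher_enumeration_oracle(a, b, c, d):
    """Exact two-sided p by full enumeration with rational arithmetic."""
    N, row1, col1 = a + b + c + d, a + b, a + c
    def prob(k):
        return (Fraction(math.comb(col1, k)) *
                math.comb(N - col1, row1 - k) / math.comb(N, row1))
    p_obs = prob(a)
    lo, hi = max(0, row1 + col1 - N), min(row1, col1)
    return float(sum(prob(k) for k in range(lo, hi + 1) if prob(k) <= p_obs))


class TestFisher:
    def test_no_association(self):
        assert fisher_2x2([[1, 1], [1, 1]]).p_value == pytest.approx(1.0)

    def test_diagonal_table_by_enumeration(self):
        # margins (2,2)x(2,2): table probabilities {1, 4, 1}/6
        assert fisher_2x2([[2, 0], [0, 2]]).p_value == pytest.approx(1 / 3)

    def test_matches_scipy_independent_route(self, rng):
        for _ in range(40):
            t = rng.integers(0, 12, size=(2, 2))
            if t.sum() == 0:
                continue
            ours = fisher_2x2(t).p_value
            theirs = stats.fisher_exact(t).pvalue
            assert ours == pytest.approx(theirs, rel=1e-9)

    def test_odds_ratio_edge_cases(self):
        assert fisher_2x2([[3, 0], [0, 3]]).aux["odds_ratio"] == np.inf
        assert fisher_2x2([[0, 3], [3, 0]]).aux["odds_ratio"] == 0.0

    def test_rejects_bad_input(self):
        with pytest.raises(ValueError):
            fisher_2x2([[1, -1], [0, 2]])
        with pytest.raises(ValueError):
            fisher_2x2([[0.5, 1], [0, 2]])
        with pytest.raises(ValueError):
            fisher_2x2([[0, 0], [0, 0]])


class TestKs:
    def test_identical_samples(self):
        r = ks_two_sample([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert r.aux["D"] == 0.0

    def test_disjoint_supports(self):
        r = ks_two_sample([0.0, 0.0, 0.0], [1.0, 1.0, 1.0])
        assert r.aux["D"] == 1.0

    def test_d_matches_ecdf_oracle(self, rng):
        x = rng.normal(size=18)
        y = rng.normal(loc=0.7, size=23)
        pooled = np.concatenate([x, y])
        d_oracle = max(abs(np.mean(x <= t) - np.mean(y <= t)) for t in pooled)
        assert ks_two_sample(x, y).aux["D"] == pytest.approx(d_oracle)

    def test_d_invariant_under_monotone_transform(self, rng):
        x = rng.normal(size=30)
        y = rng.normal(loc=0.5, size=40)
        base = ks_two_sample(x, y).aux["D"]
        for f in (np.exp, lambda v: v**3):
            assert ks_two_sample(f(x), f(y)).aux["D"] == pytest.approx(base)

    def test_empty_sample_errors(self):
        with pytest.raises(ValueError):
            ks_two_sample([], [1.0])


class TestClassMeans:
    def test_simple_means(self):
        pos, neg = class_means([0.5, 0.7, 0.1, 0.3], [True, True, False, False])
        assert pos == pytest.approx(0.6) and neg == pytest.approx(0.2)

    def test_empty_class_errors(self):
        with pytest.raises(ValueError):
            class_means([0.5, 0.7], [True, True])


class TestBinomialCorner:
    def test_all_successes_single_term(self):
        r = binomial_corner_test(10, 10, 0.5, "enrichment")
        assert r.p_value == pytest.approx(2.0**-10)

    def test_depletion_zero_successes(self):
        r = binomial_corner_test(0, 20, 0.247, "depletion")
        assert r.p_value == pytest.approx((1 - 0.247) ** 20)

    def test_matches_pmf_sum_oracle(self, rng):
        for _ in range(30):
            n = int(rng.integers(1, 40))
            k = int(rng.integers(0, n + 1))
            p0 = float(rng.uniform(0.05, 0.95))
            oracle_enr = sum(math.comb(n, i) * p0**i * (1 - p0)**(n - i)
                             for i in range(k, n + 1))
            r = binomial_corner_test(k, n, p0, "enrichment")
            assert r.p_value == pytest.approx(oracle_enr, rel=1e-10)

    @given(st.integers(1, 50), st.integers(0, 50),
           st.floats(0.01, 0.99))
    @settings(deadline=None, max_examples=50)
    def test_tail_complement_identity(self, n, k, p0):
        k = min(k, n)
        if k == 0:
            return
        enr = binomial_corner_test(k, n, p0, "enrichment").p_value
        dep = binomial_corner_test(k - 1, n, p0, "depletion").p_value
        assert enr + dep == pytest.approx(1.0, abs=1e-12)

    def test_enrichment_p_monotone_in_k(self):
        ps = [binomial_corner_test(k, 25, 0.3, "enrichment").p_value
              for k in range(26)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))

    def test_invalid_p0(self):
        with pytest.raises(ValueError):
            binomial_corner_test(1, 5, 1.0, "enrichment")


class TestQuadrants:
    spec = QuadrantSpec("rsa", "f_wt", 0.2, 50.0)

    def test_single_record_in_buried_conserved_corner(self):
        ds = make_dataset([("P", "p.A1G", dict(rsa=0.1, f_wt=80.0))])
        counts = quadrant_counts(ds, self.spec, [True])
        assert counts[("low", "high")] == (1, 1)
        assert sum(n for _, n in counts.values()) == 1

    def test_boundary_assignment_is_deterministic(self):
        ds = make_dataset([("P", "p.A1G", dict(rsa=0.2, f_wt=50.0))])
        counts = quadrant_counts(ds, self.spec, [False])
        # low-inclusive on both axes: exactly-on-cut goes to the low side
        assert counts[("low", "low")] == (0, 1)
        excl = QuadrantSpec("rsa", "f_wt", 0.2, 50.0,
                            x_low_inclusive=False, y_low_inclusive=False)
        assert quadrant_counts(ds, excl, [False])[("high", "high")] == (0, 1)

    def test_matches_exhaustive_loop_oracle(self, rng):
        rows = []
        for i in range(60):
            rows.append(("P", f"p.A{i + 1}G",
                         dict(rsa=float(rng.uniform(0, 1)),
                              f_wt=float(rng.uniform(0, 100)))))
        ds = make_dataset(rows)
        labels = rng.integers(0, 2, size=60).astype(bool)
        counts = quadrant_counts(ds, self.spec, labels)
        oracle = {c: [0, 0] for c in counts}
        for rec, lab in zip(ds, labels):
            xl = "low" if rec.rsa <= 0.2 else "high"
            yl = "low" if rec.f_wt <= 50.0 else "high"
            oracle[(xl, yl)][1] += 1
            oracle[(xl, yl)][0] += int(lab)
        assert counts == {c: tuple(v) for c, v in oracle.items()}
        assert sum(n for _, n in counts.values()) == 60

    def test_missing_features_dropped(self):
        ds = make_dataset([("P", "p.A1G", dict(rsa=0.1, f_wt=80.0)),
                           ("P", "p.A2G", dict(rsa=None, f_wt=80.0))])
        counts = quadrant_counts(ds, self.spec, [True, True])
        assert sum(n for _, n in counts.values()) == 1

    def test_absent_feature_errors(self):
        ds = make_dataset([("P", "p.A1G", dict(rsa=0.1))])
        with pytest.raises(ValueError, match="f_wt"):
            quadrant_counts(ds, self.spec, [True])


class TestBurialFractions:
    def test_all_positives_buried(self):
        ds = make_dataset([("P", "p.A1G", dict(rsa=0.05)),
                           ("P", "p.A2G", dict(rsa=0.15)),
                           ("P", "p.A3G", dict(rsa=0.9))])
        pos_b, neg_e = burial_fractions(ds, [True, True, False])
        assert pos_b == 1.0 and neg_e == 1.0

    def test_hand_counted_toy(self):
        ds = make_dataset([("P", "p.A1G", dict(rsa=0.1)),
                           ("P", "p.A2G", dict(rsa=0.5)),
                           ("P", "p.A3G", dict(rsa=0.2)),
                           ("P", "p.A4G", dict(rsa=0.7))])
        pos_b, neg_e = burial_fractions(ds, [True, True, False, False])
        assert pos_b == pytest.approx(0.5)   # one of two positives <= 0.2
        assert neg_e == pytest.approx(0.5)   # one of two negatives > 0.2

    def test_empty_class_errors(self):
        ds = make_dataset([("P", "p.A1G", dict(rsa=0.1))])
        with pytest.raises(ValueError):
            burial_fractions(ds, [True])
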