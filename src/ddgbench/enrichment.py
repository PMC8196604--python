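"""Enrichment and distribution-comparison statistics.

Tests whether putative cancer-driving variants (CMC Tier 1–3) concentrate
in particular feature regions: Fisher's exact test on 2×2 tables,
two-sample Kolmogorov–Smirnov on score distributions, one-sided binomial
tests on quadrant ("corner") cells of a 2-D feature plane (e.g. buried
RSA ≤ 0.2 × conserved f_WT > 50%), plus class-conditional means and
buried/exposed fractions.

No multiple-testing correction is applied; tests are reported
individually.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy import stats

from .variant_table import VariantDataset

logger = logging.getLogger(__name__)

Direction = Literal["enrichment", "depletion"]

#: Relative tolerance when comparing table probabilities for the
#: probability-ordering two-sided Fisher test.
_FISHER_REL_TOL = 1e-7


@dataclass(frozen=True)
class QuadrantSpec:
    """A corner of a 2-D feature plane.

    The plane is split at ``x_cut`` / ``y_cut``; each axis's low side is
    inclusive (``value <= cut``) when the corresponding ``*_low_inclusive``
    flag is True, exclusive (``value < cut``) otherwise.  The four corners
    partition all records with both features present.
    """

    x_feature: str
    y_feature: str
    x_cut: float
    y_cut: float
    x_low_inclusive: bool = True
    y_low_inclusive: bool = True

    def corner_of(self, x: float, y: float) -> tuple[str, str]:
        x_low = x <= self.x_cut if self.x_low_inclusive else x < self.x_cut
        y_low = y <= self.y_cut if self.y_low_inclusive else y < self.y_cut
        return ("low" if x_low else "high", "low" if y_low else "high")


@dataclass(frozen=True)
class EnrichmentResult:
    """One enrichment/depletion test outcome.

    ``k`` successes out of ``n`` trials against background success
    probability ``p0`` (binomial), or the analogous summary for Fisher/KS;
    ``aux`` carries the test-specific statistic (odds ratio, KS D).
    """

    k: int
    n: int
    p0: float
    direction: Direction | None
    p_value: float
    test: Literal["fisher", "binomial", "ks"]
    aux: dict = field(default_factory=dict)


def fisher_2x2(table) -> EnrichmentResult:
    """Two-sided Fisher exact test on a 2×2 contingency table.

    Uses the probability-ordering definition: the p-value sums the
    hypergeometric probabilities of all tables with the observed margins
    whose probability does not exceed the observed table's (within a
    small relative tolerance for floating-point ties).  The sample odds
    ratio is reported in ``aux`` (inf/0 allowed).
    """
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if np.any(t < 0) or not np.issubdtype(t.dtype, np.integer):
        if not np.all(t == np.floor(t)) or np.any(t < 0):
            raise ValueError("counts must be nonnegative integers")
        t = t.astype(int)
    a, b, c, d = int(t[0, 0]), int(t[0, 1]), int(t[1, 0]), int(t[1, 1])
    N = a + b + c + d
    if N == 0:
        raise ValueError("empty table")
    row1, col1 = a + b, a + c
    rv = stats.hypergeom(N, col1, row1)
    support = np.arange(max(0, row1 + col1 - N), min(row1, col1) + 1)
    pmf = rv.pmf(support)
    p_obs = rv.pmf(a)
    p = float(pmf[pmf <= p_obs * (1.0 + _FISHER_REL_TOL)].sum())
    p = min(p, 1.0)
    odds = (a * d) / (b * c) if b * c > 0 else (np.inf if a * d > 0 else np.nan)
    return EnrichmentResult(k=a, n=row1, p0=col1 / N, direction=None,
                            p_value=p, test="fisher", aux={"odds_ratio": odds})


def ks_two_sample(x, y) -> EnrichmentResult:
    """Two-sample Kolmogorov–Smirnov test.

    D is the supremum over the pooled sample of the absolute ECDF
    difference.  The p-value is exact when both samples have at most 25
    observations, asymptotic (with the effective-sample-size correction)
    otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    method = "exact" if max(x.size, y.size) <= 25 else "asymp"
    res = stats.ks_2samp(x, y, method=method)
    return EnrichmentResult(k=x.size, n=x.size + y.size, p0=0.5, direction=None,
                            p_value=float(res.pvalue), test="ks",
                            aux={"D": float(res.statistic), "method": method})


def class_means(scores, labels) -> tuple[float, float]:
    """Arithmetic mean score per class: ``(mean_positives, mean_negatives)``."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if not labels.any() or labels.all():
        raise ValueError("both classes must be nonempty")
    return float(scores[labels].mean()), float(scores[~labels].mean())


def quadrant_counts(
    ds: VariantDataset, spec: QuadrantSpec, labels
) -> dict[tuple[str, str], tuple[int, int]]:
    """Per-corner (positives k, cell size n) counts for a 2-D feature split.

    Records missing either feature are dropped (count logged); ``labels``
    is aligned to ``ds`` and Σ corner n equals the number of records
    counted.
    """
    labels = np.asarray(labels, dtype=bool)
    if len(labels) != len(ds):
        raise ValueError("labels must align with dataset")
    for feat in (spec.x_feature, spec.y_feature):
        if not any(getattr(r, feat, None) is not None for r in ds):
            raise ValueError(f"feature {feat!r} absent from dataset")
    counts = {c: [0, 0] for c in
              (("low", "low"), ("low", "high"), ("high", "low"), ("high", "high"))}
    dropped = 0
    for rec, lab in zip(ds, labels):
        x = getattr(rec, spec.x_feature)
        y = getattr(rec, spec.y_feature)
        if x is None or y is None:
            dropped += 1
            continue
        corner = spec.corner_of(float(x), float(y))
        counts[corner][1] += 1
        counts[corner][0] += bool(lab)
    if dropped:
        logger.info("quadrant_counts: dropped %d records missing %s/%s",
                    dropped, spec.x_feature, spec.y_feature)
    return {c: (k, n) for c, (k, n) in counts.items()}


def binomial_corner_test(
    k: int, n: int, p0: float, direction: Direction
) -> EnrichmentResult:
    """One-sided exact binomial test on a quadrant cell.

    With X ~ Binomial(n, p0): enrichment p-value is P[X >= k], depletion
    p-value is P[X <= k].  ``p0`` is the background positive fraction
    (e.g. 24/97 ≈ 0.247 for the CMC-annotated subset).
    """
    if not (0 < p0 < 1):
        raise ValueError(f"p0 must be in (0, 1), got {p0}")
    if not (0 <= k <= n):
        raise ValueError(f"need 0 <= k <= n, got k={k}, n={n}")
    if direction == "enrichment":
        p = float(stats.binom.sf(k - 1, n, p0))
    elif direction == "depletion":
        p = float(stats.binom.cdf(k, n, p0))
    else:
        raise ValueError(f"unknown direction {direction!r}")
    return EnrichmentResult(k=k, n=n, p0=p0, direction=direction,
                            p_value=min(p, 1.0), test="binomial",
                            aux={"expected": n * p0})


def burial_fractions(
    ds: VariantDataset, labels, rsa_cut: float = 0.2
) -> tuple[float, float]:
    """(fraction of positives buried, fraction of negatives exposed).

    Buried means RSA <= ``rsa_cut``.  Records lacking RSA are dropped
    (count logged); each class must remain nonempty.
    """
    labels = np.asarray(labels, dtype=bool)
    rsa, lab = [], []
    dropped = 0
    for rec, l in zip(ds, labels):
        if rec.rsa is None:
            dropped += 1
            continue
        rsa.append(rec.rsa)
        lab.append(l)
    if dropped:
        logger.info("burial_fractions: dropped %d records lacking rsa", dropped)
    rsa = np.asarray(rsa)
    lab = np.asarray(lab, dtype=bool)
    if not lab.any() or lab.all():
        raise ValueError("both classes must be nonempty after dropping missing RSA")
    frac_pos_buried = float(np.mean(rsa[lab] <= rsa_cut))
    frac_neg_exposed = float(np.mean(rsa[~lab] > rsa_cut))
    return frac_pos_buried, frac_neg_exposed
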