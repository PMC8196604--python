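"""End-to-end orchestration of the four analyses on a variant table.

Sections, run in order by :func:`run_all`:

1. stability regression — predicted vs experimental ΔΔG_f, pooled, after
   outlier exclusion, and per protein group;
2. destabilization classification — the ΔΔG predictor and the
   pathogenicity score as binary classifiers of ΔΔG_exp > 2 kcal/mol,
   at optimized (balanced TPR/TNR), cross-validated and fixed thresholds;
3. PCV classification — Tier 1–3 vs "Other" on the CMC-annotated subset
   with predictor-training variants excluded for the pathogenicity score;
4. enrichment — Fisher (tier × destabilization), Kolmogorov–Smirnov on
   pathogenicity scores by tier, class means, buried/exposed fractions,
   and four one-sided binomial corner tests on the (RSA, f_WT) and
   (ΔΔG_exp, score) planes.

Each section returns tidy DataFrames; run_all writes them as CSVs plus a
markdown report, and echoes config, seed and record-drop counts so the
dataset bookkeeping (e.g. 164 → 97 → 82) is auditable.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import enrichment as enr
from . import metrics as met
from .classifier import ThresholdClassifier
from .variant_table import (
    VariantDataset,
    exclude_training_variants,
    exclude_variants,
    filter_cmc_annotated,
    label_destabilizing,
    label_pcv,
    parse_variant_notation,
    read_variant_table,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AnalysisConfig:
    """Cuts, fixed thresholds and bookkeeping options for a full run.

    The fixed thresholds are the benchmark's operating points: ~1.2
    kcal/mol (ΔΔG predictor, destabilization), 0.66 (pathogenicity score,
    destabilization), 0.71 (pathogenicity score, PCV), 2.7 kcal/mol
    (ΔΔG predictor, PCV) and 0.5 (pathogenicity quadrant cut).  The
    balanced-rate optimizer is run as well and both results are reported.
    """

    outlier_keys: tuple[tuple[str, str], ...] = (("BRCA1", "p.G1788V"),)
    destab_cut: float = 2.0
    foldx_fixed_threshold: float = 1.2
    foldx_pcv_threshold: float = 2.7
    patho_destab_threshold: float = 0.66
    patho_pcv_threshold: float = 0.71
    patho_quadrant_cut: float = 0.5
    rsa_cut: float = 0.2
    fwt_cut: float = 50.0
    cv_folds: int = 5
    seed: int = 0

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, default=list)


def _reg_row(slice_name: str, m: met.RegressionMetrics) -> dict:
    return {"slice": slice_name, "n": m.n, "pearson_r": m.pearson_r,
            "spearman_rho": m.spearman_rho, "kendall_tau": m.kendall_tau,
            "rmse": m.rmse, "mae": m.mae}


def _cls_row(slice_name: str, predictor: str, mode: str,
             m: met.ClassificationMetrics, seed=None) -> dict:
    return {"slice": slice_name, "predictor": predictor, "mode": mode,
            "threshold": m.threshold, "n": m.tp + m.fp + m.tn + m.fn,
            "tp": m.tp, "fp": m.fp, "tn": m.tn, "fn": m.fn,
            "accuracy": m.accuracy, "mcc": m.mcc, "auc": m.auc,
            "tpr": m.tpr, "tnr": m.tnr, "seed": seed}


def _paired(ds: VariantDataset, xcol: str, ycol: str):
    x = ds.column(xcol)
    y = ds.column(ycol)
    ok = ~(np.isnan(x) | np.isnan(y))
    return x[ok], y[ok], int((~ok).sum())


def run_stability_eval(ds: VariantDataset, cfg: AnalysisConfig) -> pd.DataFrame:
    """Regression of predicted on experimental ΔΔG: pooled, filtered, per protein."""
    rows = []
    pred, obs, dropped = _paired(ds, "ddg_pred", "ddg_exp")
    if dropped:
        logger.info("stability_eval: dropped %d records lacking ddg pair", dropped)
    rows.append(_reg_row("pooled", met.regression_metrics(pred, obs)))

    present = {r.key for r in ds}
    removable = []
    for pid, token in cfg.outlier_keys:
        wt, pos, mut = parse_variant_notation(token)
        if (pid, wt, pos, mut) in present:
            removable.append((pid, token))
    filtered = exclude_variants(ds, removable) if removable else ds
    if len(filtered) != len(ds):
        fp, fo, _ = _paired(filtered, "ddg_pred", "ddg_exp")
        rows.append(_reg_row("pooled_no_outlier", met.regression_metrics(fp, fo)))

    for pid, group in ds.protein_groups().items():
        gp, go, _ = _paired(group, "ddg_pred", "ddg_exp")
        if gp.size < 2:
            logger.info("stability_eval: skipping %s (n=%d < 2)", pid, gp.size)
            continue
        rows.append(_reg_row(f"protein:{pid}", met.regression_metrics(gp, go)))
    return pd.DataFrame(rows)


def _classify_block(scores, labels, slice_name, predictor, fixed_threshold,
                    cfg: AnalysisConfig) -> list[dict]:
    rows = []
    if labels.all() or not labels.any():
        logger.info("classification: skipping %s/%s (single class)",
                    slice_name, predictor)
        return rows
    clf = ThresholdClassifier().fit(scores, labels)
    rows.append(_cls_row(slice_name, predictor, "optimized",
                         clf.evaluate(scores, labels)))
    n_min = int(min(labels.sum(), (~labels).sum()))
    if n_min >= cfg.cv_folds:
        cv_clf = ThresholdClassifier(cv=cfg.cv_folds,
                                     random_state=cfg.seed).fit(scores, labels)
        rows.append(_cls_row(slice_name, predictor, f"cv{cfg.cv_folds}",
                             cv_clf.evaluate(scores, labels), seed=cfg.seed))
    fixed = ThresholdClassifier(threshold=fixed_threshold).fit(scores, labels)
    rows.append(_cls_row(slice_name, predictor, "fixed",
                         fixed.evaluate(scores, labels)))
    return rows


def run_destab_classification(ds: VariantDataset, cfg: AnalysisConfig) -> pd.DataFrame:
    """ΔΔG predictor and pathogenicity score as destabilization classifiers."""
    sub, labels = label_destabilizing(ds, cfg.destab_cut)
    rows: list[dict] = []
    for predictor, col, fixed in (("ddg_pred", "ddg_pred", cfg.foldx_fixed_threshold),
                                  ("patho_score", "patho_score",
                                   cfg.patho_destab_threshold)):
        scores = sub.column(col)
        ok = ~np.isnan(scores)
        rows += _classify_block(scores[ok], labels[ok], "pooled", predictor,
                                fixed, cfg)
    # protein-specific thresholds for the groups with most variants
    sizes = {pid: len(g) for pid, g in sub.protein_groups().items()}
    for pid in sorted(sizes, key=sizes.get, reverse=True)[:2]:
        group = sub.protein_groups()[pid]
        gsub, glab = label_destabilizing(group, cfg.destab_cut)
        scores = gsub.column("ddg_pred")
        ok = ~np.isnan(scores)
        rows += _classify_block(scores[ok], glab[ok], f"protein:{pid}",
                                "ddg_pred", cfg.foldx_fixed_threshold, cfg)
    return pd.DataFrame(rows)


def run_pcv_classification(ds: VariantDataset, cfg: AnalysisConfig) -> pd.DataFrame:
    """Tier 1–3 vs "Other" classification on the CMC-annotated subset."""
    annotated = filter_cmc_annotated(ds)
    rows: list[dict] = []

    # pathogenicity score: stringent evaluation excludes its training variants
    evalset = exclude_training_variants(annotated)
    labels = label_pcv(evalset)
    scores = evalset.column("patho_score")
    ok = ~np.isnan(scores)
    rows += _classify_block(scores[ok], labels[ok],
                            f"cmc_no_training(n={int(ok.sum())})", "patho_score",
                            cfg.patho_pcv_threshold, cfg)

    # ΔΔG predictor needs no training exclusion
    labels_all = label_pcv(annotated)
    dscores = annotated.column("ddg_pred")
    ok = ~np.isnan(dscores)
    rows += _classify_block(dscores[ok], labels_all[ok],
                            f"cmc(n={int(ok.sum())})", "ddg_pred",
                            cfg.foldx_pcv_threshold, cfg)
    return pd.DataFrame(rows)


def run_enrichment(ds: VariantDataset, cfg: AnalysisConfig) -> pd.DataFrame:
    """All enrichment statistics on the CMC-annotated subset."""
    annotated = filter_cmc_annotated(ds)
    labels = label_pcv(annotated)
    if not labels.any() or labels.all():
        raise ValueError("enrichment requires both Tier 1-3 and 'Other' records")
    rows = []

    def res_row(name: str, r: enr.EnrichmentResult) -> dict:
        stat = r.aux.get("odds_ratio", r.aux.get("D", r.aux.get("expected", np.nan)))
        return {"test": r.test, "slice": name, "k": r.k, "n": r.n, "p0": r.p0,
                "direction": r.direction or "", "statistic": stat,
                "p_value": r.p_value}

    # Fisher: tier membership x high destabilization
    ddg = annotated.column("ddg_exp")
    ok = ~np.isnan(ddg)
    destab = ddg[ok] > cfg.destab_cut
    lab = labels[ok]
    table = [[int((lab & destab).sum()), int((lab & ~destab).sum())],
             [int((~lab & destab).sum()), int((~lab & ~destab).sum())]]
    rows.append(res_row("tier_x_destabilizing", enr.fisher_2x2(table)))

    # KS + class means on the pathogenicity score
    patho = annotated.column("patho_score")
    ok = ~np.isnan(patho)
    ks = enr.ks_two_sample(patho[ok & labels], patho[ok & ~labels])
    rows.append(res_row("patho_by_tier", ks))
    mean_pos, mean_neg = enr.class_means(patho[ok], labels[ok])
    rows.append({"test": "class_mean", "slice": "patho_by_tier",
                 "k": int(labels[ok].sum()), "n": int(ok.sum()), "p0": np.nan,
                 "direction": "positives", "statistic": mean_pos,
                 "p_value": np.nan})
    rows.append({"test": "class_mean", "slice": "patho_by_tier",
                 "k": int((~labels[ok]).sum()), "n": int(ok.sum()), "p0": np.nan,
                 "direction": "negatives", "statistic": mean_neg,
                 "p_value": np.nan})

    # burial fractions
    frac_pos, frac_neg = enr.burial_fractions(annotated, labels, cfg.rsa_cut)
    rows.append({"test": "burial_fraction", "slice": "pcv_buried",
                 "k": np.nan, "n": len(annotated), "p0": np.nan,
                 "direction": "positives", "statistic": frac_pos, "p_value": np.nan})
    rows.append({"test": "burial_fraction", "slice": "benign_exposed",
                 "k": np.nan, "n": len(annotated), "p0": np.nan,
                 "direction": "negatives", "statistic": frac_neg, "p_value": np.nan})

    # four binomial corner tests; p0 = global positive fraction of the subset
    p0 = float(labels.mean())
    struct_spec = enr.QuadrantSpec("rsa", "f_wt", cfg.rsa_cut, cfg.fwt_cut)
    qc = enr.quadrant_counts(annotated, struct_spec, labels)
    k, n = qc[("low", "high")]  # buried & conserved
    rows.append(res_row("buried_conserved",
                        enr.binomial_corner_test(k, n, p0, "enrichment")))
    k, n = qc[("high", "low")]  # exposed & variable
    rows.append(res_row("exposed_variable",
                        enr.binomial_corner_test(k, n, p0, "depletion")))

    func_spec = enr.QuadrantSpec("ddg_exp", "patho_score", cfg.destab_cut,
                                 cfg.patho_quadrant_cut)
    qf = enr.quadrant_counts(annotated, func_spec, labels)
    k, n = qf[("high", "high")]  # destabilizing & predicted pathogenic
    rows.append(res_row("destab_pathogenic",
                        enr.binomial_corner_test(k, n, p0, "enrichment")))
    k, n = qf[("low", "low")]
    rows.append(res_row("stable_benign",
                        enr.binomial_corner_test(k, n, p0, "depletion")))
    return pd.DataFrame(rows)


@dataclass
class AnalysisReport:
    """All section tables plus provenance for one full run."""

    stability: pd.DataFrame
    destab_classification: pd.DataFrame
    pcv_classification: pd.DataFrame
    enrichment: pd.DataFrame
    config: AnalysisConfig
    provenance: tuple[str, ...] = ()

    def to_markdown(self) -> str:
        parts = ["# Variant-impact analysis report", ""]
        for title, df in (("Stability regression", self.stability),
                          ("Destabilization classification",
                           self.destab_classification),
                          ("PCV classification", self.pcv_classification),
                          ("Enrichment", self.enrichment)):
            with pd.option_context("display.float_format", "{:.4g}".format,
                                   "display.width", 200,
                                   "display.max_columns", 50):
                body = df.to_string(index=False)
            parts += [f"## {title}", "", "```", body, "```", ""]
        parts += ["## Provenance", "", "```json", self.config.to_json(), "```", ""]
        parts += [f"- {p}" for p in self.provenance]
        return "\n".join(parts) + "\n"

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.stability.to_csv(out / "stability.csv", index=False)
        self.destab_classification.to_csv(out / "destab_classification.csv",
                                          index=False)
        self.pcv_classification.to_csv(out / "pcv_classification.csv", index=False)
        self.enrichment.to_csv(out / "enrichment.csv", index=False)
        (out / "report.md").write_text(self.to_markdown(), encoding="utf-8")


def run_all(ds: VariantDataset, cfg: AnalysisConfig | None = None,
            out_dir: str | Path | None = None) -> AnalysisReport:
    """Run all four sections; optionally write CSVs and the markdown report."""
    cfg = cfg or AnalysisConfig()
    sections = {}
    for name, fn in (("stability", run_stability_eval),
                     ("destab_classification", run_destab_classification),
                     ("pcv_classification", run_pcv_classification),
                     ("enrichment", run_enrichment)):
        try:
            sections[name] = fn(ds, cfg)
        except Exception as e:
            raise RuntimeError(f"analysis section {name!r} failed: {e}") from e
    report = AnalysisReport(config=cfg, provenance=ds.provenance, **sections)
    if out_dir is not None:
        report.write(out_dir)
    return report


def run_from_table(path: str | Path, cfg: AnalysisConfig | None = None,
                   out_dir: str | Path | None = None) -> AnalysisReport:
    """Convenience: read a variant table from disk and run everything."""
    return run_all(read_variant_table(path), cfg, out_dir)
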