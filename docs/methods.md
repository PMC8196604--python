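# Methods

## Problem setting

A curated benchmark of single amino-acid variants (SAVs) in
cancer-related proteins pairs each variant with an experimental folding
free-energy change ΔΔG_f = ΔG_f(mut) − ΔG_f(wt) in kcal/mol (positive =
destabilizing), an optional melting-temperature change ΔT_m (°C), a
predicted ΔΔG_f (a FoldX-style estimate averaged over structural
models), a pathogenicity score in [0, 1] (a Meta-SNP-style
meta-predictor output), the site's relative solvent accessibility (RSA)
and the wild-type residue frequency f_WT (percent) in a multiple
sequence alignment of homologs, plus a Cancer Mutation Census (CMC)
annotation: Tier 1–3 (driver evidence, here called putative
cancer-driving variants, PCVs), "Other" (treated as benign) or
unannotated.  The package evaluates the predictors on such a table and
tests whether PCVs concentrate in destabilizing / buried / conserved
regions.  It does not run FoldX, Meta-SNP or DSSP: their outputs are
inputs.

## Data model and filtering conventions

- Missing numeric cells stay missing (never imputed, never 0); every
  analysis drops the records lacking its required fields and logs the
  count, so the subset bookkeeping (e.g. 164 total → 97 CMC-annotated →
  82 after removing the pathogenicity predictor's 15 training variants)
  is auditable from the logs and the dataset provenance list.
- Duplicate (protein, wt, position, mut) keys are a hard error; a
  curated table has none, and silent merging would corrupt counts.
- Variant tokens are one-letter, the "p." prefix optional on input and
  emitted on output.  Training-set membership is an input column, not a
  hard-coded list.
- p53's DNA-binding and oligomerization domains are distinct protein
  groups throughout.

## Classification conventions

One strict rule everywhere: predicted positive ⇔ score > threshold, and
the destabilization label is ΔΔG_exp > 2.0 kcal/mol — a record exactly
at a boundary is negative.  Balanced-rate threshold selection minimizes
|TPR − TNR| over the midpoints between consecutive sorted unique scores
plus one candidate below the minimum (everything positive) and one at
the maximum (everything negative under the strict rule); ties break by
larger MCC, then smaller threshold, making the result deterministic and
order-independent.  Cross-validated selection uses stratified, seeded
k-fold (default k = 5), optimizes on each set of k−1 training folds and
takes the median of the fold thresholds; how fold results combine is a
design choice of this package, and both the CV and the full-data
thresholds are reported side by side.  MCC is defined as 0 when a
confusion-matrix marginal is 0.  Kendall's correlation is the
tie-corrected τ_b.  Fixed operating points carried in the analysis
config: 1.2 kcal/mol (stability predictor vs destabilization), 0.66 and
0.71 (pathogenicity score vs destabilization and PCV), 2.7 kcal/mol
(stability predictor vs PCV), 0.5 (pathogenicity quadrant cut).

## Enrichment statistics

- Fisher's exact test (two-sided) uses the probability-ordering
  definition — sum the hypergeometric probabilities of all tables with
  the observed margins that are no more probable than the observed one,
  with a 1e-7 relative tolerance for floating-point ties.  This is the
  most common convention for the two-sided exact test.
- The two-sample Kolmogorov–Smirnov p-value is exact for samples of at
  most 25 each, otherwise asymptotic with the effective-sample-size
  correction; D is always the exact ECDF supremum.
- Quadrant tests split a feature plane at configurable cuts (defaults:
  RSA ≤ 0.2 = buried, f_WT > 50% = conserved, ΔΔG_exp > 2 kcal/mol,
  score > 0.5).  Low sides are boundary-inclusive by default and
  configurable per axis.  Each corner cell with n records and k PCVs is
  tested one-sided against X ~ Binomial(n, p₀) — enrichment P[X ≥ k],
  depletion P[X ≤ k] — with p₀ defaulting to the analyzed subset's PCV
  fraction (24/97 ≈ 0.247 at the benchmark's composition), overridable.
- No multiple-testing correction is applied; tests are reported
  individually.

## Structural and evolutionary features

RSA = ASA / maxASA(residue), clamped to [0, 1].  The normalization
defaults to the theoretical maximum-ASA scale of Tien et al. (2013),
with the Sander–Rost (1994) scale selectable; the choice shifts RSA
slightly and can move sites across the 0.2 boundary, which is why it is
explicit.  f_WT is the percentage of alignment-column residues equal to
the wild type, with gap symbols excluded from the denominator (a design
choice; column order is irrelevant).  DSSP output files are parsed for
the per-residue ACC column via biopython; alignments are read with
Bio.AlignIO.  These helpers prepare input tables — the pipeline's
primary path reads `rsa` and `f_wt` as precomputed columns.

## Synthetic data generator

The generator produces datasets with the statistical structure the
analysis assumes, so the whole pipeline is testable without a
proprietary table, and parameter recovery is the acceptance surface.

Per record: PCV status ~ Bernoulli(π = 0.247), tier uniform over 1–3
for positives; a latent "highly destabilizing" class drawn conditional
on PCV status (P = 0.58 for PCVs, 0.28 otherwise) — this coupling is
what gives the Fisher and corner tests something to find; ΔΔG_exp from
class-conditional Gaussians (destabilizing: mean 3.8, sd 1.4; stable:
mean 0.7, sd 0.8 kcal/mol); the predicted ΔΔG adds independent Gaussian
noise with sd = σ_signal·√(1/r² − 1), the closed form that makes
corr(X, X+ε) equal the target r (default 0.5) — analytic calibration was
chosen over mimicking a real predictor's heavy-tailed error structure,
testability over realism.  Bounded scores use Beta laws parameterized by
mean and concentration (α = μκ, β = (1−μ)κ): pathogenicity means
0.71 / 0.47 with κ = 8; RSA Beta(0.8, 3.2) for PCVs (buried fraction
≈ 0.6) vs Beta(1.2, 1.8) for the rest (exposed fraction ≈ 0.74); f_WT
Beta(4.0, 1.5) vs Beta(1.5, 2.5).  These class-conditionals were fixed
once from the targeted fractions; the marginal shapes beyond those
targets are design choices, not measured facts.

`benchmark_dataset(seed)` is the study-shaped preset: exactly 164
variants over 11 proteins (ten of 15, one of 14), 97 annotated (24
Tier 1–3 + 73 "Other"), 53 records above the 2 kcal/mol cut (the
class-conditional Gaussians are truncated at the boundary so the count
is deterministic), and 15 training flags among the annotated records.
Label layouts are drawn without replacement so counts are forced and
count-based tests are deterministic, while all values remain random.
Same config + seed ⇒ bit-identical dataset and ledger.

What the generator does *not* emulate: per-protein heterogeneity of the
ΔΔG distributions, the stability predictor's asymmetric heavy right
tail (the single-outlier pathology that motivates outlier exclusion),
correlated errors between predictors, and annotation noise.  Passing
tests therefore demonstrate that the machinery is correct and has the
expected power under its assumed data-generating process — not that any
particular real predictor attains these numbers on real data.

## Problem sizes and numerical choices

Tests and the acceptance script run at the study scale (164 variants
per dataset); recovery checks average 200 replicates, at which scale the
Monte-Carlo standard error of the mean Pearson estimate (≈ 0.004) is
well inside the ±0.05 acceptance band, and the class-mean error
(≈ 0.003) inside ±0.03.  The injected-enrichment power check uses 100
replicates with Beta class-conditionals chosen for strong
buried/conserved separation.  Shuffled-label null checks use 200
permutations; the one-sided binomial p-value is discrete and therefore
conservative under the null (its null mean exceeds 1/2 by half the
point-mass collision probability), so uniformity is asserted as "no
excess of small p-values and mean in a band around 1/2", not as exact
uniformity.  Degenerate inputs error loudly: single-class labels for
AUC/threshold search, empty samples for KS, all-gap columns for f_WT,
zero-variance vectors report NaN correlations with a warning while the
error metrics stay defined.

## Known limitations

- The balanced-rate criterion targets |TPR − TNR| only; cost-sensitive
  thresholds are out of scope.
- No confidence intervals on metrics; no multi-class support.
- The generator's independence assumptions (features independent within
  class) make quadrant enrichments a direct product of the marginals;
  real data may couple RSA and conservation more intricately.
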