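# Methods

This note documents the models, defaults, and numerical choices behind
`revsig`, and what the synthetic-data validation does and does not
demonstrate.

## Scope and data model

The pipeline starts at gene-level (and exon/junction-level) count matrices;
read processing and alignment are out of scope. Counts are genes x samples
with integer entries; sample annotations carry genotype (`WT` /
`disease`), dose (`veh` / `low` / `high`), tissue, and optionally a study
id. Gene identifiers are opaque, case-sensitive strings — cross-dataset
harmonization (ortholog mapping, symbol conversion) is the caller's
responsibility. Named contrasts: A disease:veh vs WT:veh, B disease:high
vs disease:veh, C disease:low vs disease:veh, D WT:high vs WT:veh, and E =
D evaluated on a second (blood) tissue; all are plain two-group designs
with no special-case code.

## Preprocessing

* **Low-count filter**: genes with mean count across all samples below 10
  are removed (a mean of exactly 10 is kept). The filter is applied per
  tissue to the whole matrix before any contrast.
* **TMM factors**: reference sample = the one whose 75th-percentile count
  fraction is closest to the mean of those. Per sample, M = log2 ratio of
  count fractions vs the reference and A = mean log2 abundance are computed
  over genes expressed in both; 30% of each M tail and 5% of each A tail
  are trimmed (rank-based, as in the published TMM convention), and the
  factor is 2 to the inverse-variance-weighted mean of the retained M
  (binomial delta-method variances). Factors are rescaled to geometric
  mean 1. A sample sharing no expressed genes with the reference gets
  factor 1 with a warning. Note the factors are exactly invariant to
  rescaling a sample's counts only at the M-value level; the precision
  weights depend on raw counts, so the factor moves by O(1/count) — the
  tests assert near-invariance.
* **log-CPM**: `log2((count + 0.5) / (effective library size + 1) * 1e6)`.
* **PCA outlier screen**: samples farther than 3 robust SDs (median/MAD per
  component) from the centroid in PC1/PC2 of the log-CPM matrix are
  *flagged only*; removal is an explicit caller decision, since no
  principled automatic cutoff exists for small designs.

## Differential expression

Per gene, weighted least squares on the design matrix with precision
weights from the mean-variance trend: unweighted residual sds are computed
first, sqrt(sd) is smoothed against average log2 count by lowess (span
0.5, the conventional default), each observation's fitted log-count is
looked up on the trend (linear interpolation, clamped at the ends,
predicted sqrt-sd floored at 1e-4), and the weight is predicted sd^-4.

The variance prior (d0, s0²) is estimated by moment-matching log s² to a
scaled-F law via the digamma/trigamma closed form, with the trigamma
inverse solved by Newton iteration; non-positive excess variance falls back
to complete shrinkage (d0 = infinite) with a warning. Residual variances
are floored at 1e-8 before moderation. Moderated t uses d0 + d degrees of
freedom (normal when infinite). p-values are BH-adjusted per contrast.
Log2 fold changes are on the log-CPM scale; "linear fold change" filters
use 2^log2FC, with DEG thresholds |linear FC| > 1.25 (strict) and adjusted
p < 0.05 (strict).

## Signatures, meta-analysis, reversal

A signature maps gene -> moderated t for one contrast; the gene universe is
whatever survived that dataset's own filter (no imputation). Two studies
combine by unweighted signed Stouffer over shared genes (sample-size
weighting available); unweighted is the default because the combined
studies may come from different platforms with non-comparable effect
scales.

Reversal of disease signature d by treatment signature t:

* **Cosine** over the shared-gene intersection (all filtered genes, not
  DEGs only — restricting to DEGs is an option); negative = reversal.
  Significance by permuting the treatment signature's gene-score
  assignment, one-sided toward reversal, +1 smoothing (floor
  1/(n_perm+1)).
* **Directional enrichment**: the disease up/down DEG sets are scored in
  the treatment ranking by the weighted running-sum statistic; reversal
  requires the up set negatively enriched AND the down set positively
  enriched, both BH-significant across the tested family. The verdict
  "reversed" requires both directions — one-sided evidence is not called.

**Shared-arm caveat.** Within a single cohort, the disease contrast
(disease:veh vs WT:veh) and a treatment contrast (disease:dose vs
disease:veh) share the vehicle-disease samples, so their noise is
negatively correlated and the cosine has a negative expectation (~ -0.5 at
these group sizes) even with no treatment effect. The pipeline's
within-study reversal report therefore overstates reversal in absolute
terms (as any within-study design does); the validation suite instead
derives disease and treatment signatures from independent simulated
cohorts sharing the same planted truth, where a no-effect control gives
cosine ~ 0 and nominal false-positive rates. Users comparing against an
independently assembled disease signature (the recommended design) are in
the calibrated regime.

## Enrichment

* **Preranked running sum**: genes ranked by decreasing score, ties broken
  by gene id. Hits add |score|^p / sum over hits (p = 1 default; p = 0
  exposed), misses subtract 1/(N − n_hits); ES is the signed maximal
  deviation, with exact |max| = |min| ties resolved positive (1e-12
  tolerance so float noise cannot flip the sign). Null = ES of random
  same-size gene sets (gene-tag permutation — preranked input has no
  sample labels); NES divides by the mean |null ES| of matching sign;
  permutation p is two-sided by sign class with +1 smoothing; BH across
  the sets tested in one call (the full ES-pooling FDR machinery of the
  original tool is not replicated).
* **Over-representation**: one-sided hypergeometric tail of the overlap
  between a DEG list and each set (intersected with the user-supplied
  universe), BH across sets. This is a local stand-in for web-service
  enrichment tools; their rank-corrected statistics are not replicated.

## Differential exon/junction usage

Per feature, the 2n observations (this-feature count, rest-of-gene count
per sample) follow an NB log-linear model with intercept, sample effects,
a feature-part effect, and a part x condition interaction; the interaction
is the usage log-fold-change and is tested by a 1-df LRT against the
nested model. Fits use batched IRLS across features (shared design,
per-feature dispersion, ridge 1e-9, linear predictor clipped at ±30).

Dispersion: per-feature method of moments on the residuals of the
full-mean model (conditional on fitted means, so variation the design
absorbs — library size, gene-level expression change — does not inflate
it), estimated separately for the feature and rest-of-gene observation
parts (their overdispersion genuinely differs), df-corrected, clipped to
[1e-8, 10], then moderated by equal-weight averaging with the across-
feature median of each part. The moderation matters: raw per-feature
estimates from ~32 observations are noisy enough that their underestimates
inflate the extreme tail of the LRT (breaking null calibration at the
multiple-testing level) while overestimates cost power. There is no
abundance-trend shrinkage. Features with mean count below 5 and
single-feature genes are skipped and counted in the report. A gene is
DUEJ-positive when any feature's BH-adjusted p is below alpha (min-p per
gene); usage reversal requires the disease gene's top feature to be
significant in both contrasts with opposite-signed interaction
coefficients.

## Synthetic data generator

The generator emulates a chronic-dosing design: WT and disease genotypes x
vehicle/low/high arms, `n_per_group` samples per cell (default 8).

* Baseline per-gene means: lognormal(meanlog 5, sdlog 1.5) — a typical
  bulk dynamic range; means are rescaled so each sample's expected total
  equals its library size.
* NB dispersions: lognormal(meanlog −1.5, sdlog 0.5), Var = mu + phi mu²
  — the typical bulk RNA-seq range.
* Library sizes: lognormal(log 1e7, sigma 0.25).
* Disease effect: a fraction (default 0.1) of genes gets log2FC ~ N(0, 1)
  applied to all disease-genotype samples.
* Reversal: a fraction (default 0.8) of disease genes is pulled back in
  treated disease samples: treated mean = baseline * 2^(lfc * (1 − kappa)),
  kappa in [0,1] per dose (defaults 0.3 low, 0.8 high) — kappa = 1 is full
  reversal, dose-dependence is encoded only through kappa. WT samples are
  unaffected by treatment, matching the empirical finding that treatment
  effects concentrate in the disease genotype.
* Two-study mode: per-gene disease log2FCs for the two cohorts are a
  bivariate-normal draw with a configurable correlation; noise, library
  sizes and dispersions are independent; only vehicle arms are generated
  (case/control cohorts have no dosing).
* Feature-level mode: per gene, totals are split across K features (default
  4) by Dirichlet-multinomial around gene-specific expected proportions
  (Dirichlet concentration 50 — moderate overdispersion). Usage-shift
  genes get one randomly chosen feature's expected proportion moved by a
  logit-scale delta (default 1.0) in the treated condition, with the other
  features rescaled so gene totals are unchanged in expectation. The
  treated condition can additionally carry gene-level expression effects
  (via the disease-fraction parameters) so the usage test's specificity
  against pure expression change is exercisable.
* Determinism: one integer seed drives everything, bit-reproducibly. A
  separate `noise_seed` optionally splits the truth stream (gene
  parameters, planted effects) from the noise stream (library sizes,
  count draws) so independent cohorts can share one ground truth.

What the generator does **not** emulate: batch effects beyond library
size, correlated genes/co-expression modules, GC/length biases,
ambient/contamination, outlier samples, or annotation errors. Passing
tests on this generator demonstrate internal statistical correctness and
calibration of the methods under an idealized NB world — not robustness to
the full messiness of real data.

## Validation problem sizes

The test suite and `scripts/acceptance.py` run at sizes chosen to give
stable Monte-Carlo estimates in a few CPU-minutes: DE calibration and
reversal detection at 2,000 genes and 8 samples per arm (50 replicates in
the suite, 12 in the acceptance script); usage-test calibration at 300-400
genes x 3-4 features; enrichment-null uniformity over 500 random
set/score draws at 200 genes; oracle-equivalence checks over 200 random
small instances per primitive. Detection rates are reported as fractions
of replicates; calibration checks compare observed rates to the nominal
level plus twice the binomial standard error.

## Known limitations

* Recovery of planted effects is bounded by the generator's own noise: at
  dispersion ~ e^-1.5 and 8 samples per arm, the |t|-ranking AUC for
  disease genes with N(0,1) effects has a theoretical ceiling near 0.80 —
  increasing group size or lowering dispersion raises it; this is a
  property of the study conditions, not the estimator.
* The usage model is a two-part (feature vs rest-of-gene) simplification
  of a full multi-feature GLM; exact parity with flat-GLM tools is a
  non-goal, and per-gene significance is min-p (anti-conservative at the
  gene level relative to a joint test, conservative in power).
* The enrichment module's BH-across-sets differs from the original
  preranked tool's NES-pooled FDR; q-values are not comparable between
  the two, though orderings generally agree.
* Outlier handling is screen-only; covariate adjustment beyond the group
  factor is available through the design-matrix API but no covariates are
  assumed by default.
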