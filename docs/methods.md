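# Methods

## The question and the model

Two measurements of one underlying character — say, a manually measured and
an image-predicted tassel length on the same inbred lines — can be modeled as
two traits with the *same* causal loci and effect sizes but different
heritabilities: each measurement adds its own error variance on top of the
shared genetic signal. The framework asks whether the difference in
heritability D = |h²ₐ − h²ᵦ| is large enough that genome-wide association
results for the two measurements should be expected to differ significantly.

A simulated trait on an n-line panel is

    yᵢ = Σₗ wᵢₗ aₗ + εᵢ,   l = 1..NCL

with wᵢₗ = (gᵢₗ − 2p)/√(2p(1−p)) the standardized major-allele dosage
(p the major-allele frequency), aₗ ~ N(0, σ²ₐ) the allelic effects, and
εᵢ ~ N(0, σ²ε). The genetic variance σ²g is the sample variance (denominator
n − 1) of the genetic values Σₗ wᵢₗ aₗ, and the noise variance is set from
the target heritability: σ²ε = σ²g/h² − σ²g. Because σ²ε is tuned to σ²g, the
effect-variance default σ²ₐ = 10 is a scale convention, not a substantive
parameter.

Two modeling commitments matter downstream:

- **Causal loci and effects are drawn once per NCL level** and reused for
  every h² level and replicate; replicates with the same (NCL, h²) differ
  only in ε. This makes the case/control labeling identical across all traits
  of an NCL level, which the *paired* AUC comparison requires. Causal sets
  for different NCL levels are drawn independently (nesting them is an
  equally defensible choice; nothing downstream depends on it). A
  `redraw_effects_per_cell` flag exists for sensitivity analysis but breaks
  the pairing and is never the default.
- **Standardization uses the Hardy–Weinberg-form s.d. √(2p(1−p))** exactly as
  written above, even on a fully inbred panel where the empirical dosage
  s.d. is √2 larger. The choice only rescales effects jointly, and σ²ε
  tracking σ²g absorbs the rescaling.

## Synthetic panel

The generator emulates an inbred diversity panel: per-SNP minor-allele
frequencies drawn from a configurable spectrum (default uniform on
[0.05, 0.5] — the real spectrum of any given panel is unknown, and a flat
spectrum keeps most SNPs informative), alleles sampled through a Gaussian
copula, per-locus autozygosity probability F (default 1: fully homozygous
dosages {0, 2}), optional missingness (default 0.3%, the residual
missingness level typical after haplotype imputation) followed by per-SNP
mean imputation, and removal of SNPs with minor-allele frequency strictly
below 0.02. Optional LD blocks give consecutive SNPs within a block a shared
latent haplotype with correlation ρ.

What the generator does **not** emulate: realistic LD decay and population
structure (the block model is crude and off by default), ascertainment of
SNPs from expressed genes, relatedness structure among lines, and allele
frequency spectra shaped by selection. Consequently, passing tests show the
*statistical machinery* behaves correctly under a clean inbred-panel null;
they do not certify the magnitudes (AUC levels, null thresholds, Z~D slopes)
that a specific real panel with real LD would produce. Published thresholds
and predicted-Z ranges for a real 942-line maize panel depend on that LD
structure and are not reproducible from the synthetic panel; the package
reproduces the design counts, the calibration guarantee and the qualitative
trends instead.

## Mixed-model scan

Per trait the model is y = 1μ + xβ + u + e with u ~ N(0, σ²ᵤK) and
e ~ N(0, σ²ₑI). K is the VanRaden genomic relationship matrix
K = MMᵀ / (2Σⱼfⱼ(1−fⱼ)) computed from 10,000 randomly sampled SNPs (capped
at the panel size; M centered by 2fⱼ), computed once per panel and reused
for every trait. No covariates (no principal components) enter the model,
and no compression/grouping of individuals is applied — this is the plain
individual-level mixed model.

Estimation uses the eigendecomposition K = USUᵀ (computed once and cached;
eigenvalues clipped at 0). With λ = σ²ᵤ/σ²ₑ and weights 1/(λsᵢ + 1), REML for
the null model is a 1-D problem in λ: a log₁₀ grid of 100 points on
[−5, 5] plus λ = 0, followed by bounded Brent refinement between the best
grid point's neighbours (tolerance 10⁻⁶). The scan then fixes λ per trait
(P3D/EMMAX) and tests each marker by GLS in the rotated basis — three
vectorized reductions per genome — with a Wald t on n − 2 degrees of
freedom, residual scale re-estimated per marker. For a 1-df contrast this t²
is the F statistic mainstream MLM software reports, so the p-values agree.
Monomorphic markers are collinear with the intercept; they are flagged and
assigned p = 1 rather than raising, so a scan never dies mid-genome. An
exact per-marker REML mode exists (`per_marker_reml=True`) and is orders of
magnitude slower; the P3D scan is the default and the tested path.

p = 0 underflow is mapped to the smallest positive double before the
−log₁₀ transform.

## ROC, AUC and the DeLong paired test

Causal SNPs are cases, all other SNPs controls, −log₁₀(p) the predictor.
The empirical curve is evaluated at every distinct score (sensitivity:
fraction of cases ≥ threshold; specificity: fraction of controls <
threshold). The AUC is the Mann–Whitney statistic with midrank tie handling
(ψ = ½ on ties), computed in O(N log N) from ranks; it equals the
trapezoidal area under the empirical curve exactly. Replicate curves are
averaged for display by interpolating each curve's sensitivity onto a fixed
specificity grid (step 0.002, linear interpolation, vertical steps resolved
to the higher sensitivity) and taking pointwise means; the averaging
abscissa is a display convention and never enters inference.

Two traits sharing an NCL level are compared with DeLong's estimator:
per-case components V₁₀(i) = (1/n)Σⱼψ(Xᵢ, Yⱼ) and per-control V₀₁(j), their
2×2 sample covariance matrices S₁₀ and S₀₁ across the two curves, covariance
estimate S₁₀/m + S₀₁/n, and Z = (AUC₁ − AUC₂)/√(var₁ + var₂ − 2cov₁₂). If
the variance of the difference is numerically zero (e.g. identical score
vectors) Z is defined as 0 and flagged degenerate. Components are computed
once per trait, so the all-pairs sweep over T traits costs
O(T·N log N + T²·N).

## Empirical null calibration and prediction

GWAS scores are dependent across SNPs (LD, shared kinship correction), so Z
is not referred to its asymptotic normal. Instead, comparisons between
traits simulated with identical parameters (D = 0) form an empirical null;
the α = 0.05 thresholds are the 2.5th and 97.5th percentiles of these null
Z values (linear interpolation between order statistics — the percentile
definition matters at small null sample sizes and is fixed here; a warning
fires below 40 null comparisons).

Comparisons are oriented higher-h² trait minus lower-h² trait; equal-h²
pairs are oriented by ascending replicate index. The convention only affects
the sign symmetry of the (approximately symmetric) null.

Per NCL level, ordinary least squares of Z on D (intercept included, all
pairs pooled; a flag excludes the D = 0 pairs) gives the prediction line.
For a real pair of measurements the heritability difference can be supplied
either as two heritabilities (D computed as their absolute difference) or as
D directly — the latter matters when D was derived from unrounded
heritability estimates that rounding would distort. Predictions are point
estimates compared against the null thresholds; no prediction interval is
attached, and no multiple-testing correction is applied across characters.

## Pipeline and reproducibility

The pipeline is file-based: every stage reads the previous stage's TSV
tables from the output directory and writes its own, so any stage can be
rerun in isolation. Per-stage seeds derive from the master seed plus a CRC
of the stage name. All floats are written with a fixed `%.10g` format, making
a rerun with the same config byte-identical. A `manifest.json` records the
config, stage seeds, library versions, table row counts and per-stage wall
clock.

Problem sizes: the package's desk preset is a 500 × 5,000 panel with NCL
{10, 100}, h² 0.2–0.9 and 5 replicates — the scale at which the test suite
exercises the full pipeline and at which the calibration and trend
properties are verified (minutes on one CPU). The published-study scale
(942 lines × 529,018 SNPs × 270 traits) is supported by the same code paths
but is a cluster-sized job.

## Known limitations

- No LD realism; the empirical null width on real data reflects LD that the
  synthetic panel lacks, so synthetic thresholds should not be transferred
  to real panels — refit them on the panel of interest.
- The trait model is strictly additive (no dominance, epistasis,
  genotype-by-environment); measurement error is i.i.d. Gaussian and
  uncorrelated between the paired traits.
- The P3D approximation slightly misestimates per-marker variance components
  when a marker explains substantial variance; this is the standard
  trade-off and the exact mode exists for spot checks.
- AUC summarizes the whole curve; two curves with equal AUC can differ in
  the low-FPR region a GWAS practitioner cares most about. Partial-area
  summaries are out of scope.
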