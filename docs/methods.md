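# Methods

This note documents the statistical procedures, the synthetic-data model,
the numerical choices, and the limitations of `pgxpersona`.

## The analysis

The pipeline asks whether a polygenic score (PGS) for a personality trait
predicts a binary SSRI treatment outcome (response: ≥50% symptom reduction;
remission: symptom score below a fixed cutoff), and which individual
variants drive shared signal between the trait and the outcome.

**Scoring.** Discovery-GWAS effect sizes (per-allele betas for the counted
allele) weight the dosages of an LD-clumped SNP set. Clumping is greedy by
ascending discovery p: the best remaining variant becomes an index SNP and
removes every variant on the same chromosome within ±250 kb whose in-cohort
dosage r² is ≥ 0.1. For each cutoff P_T in
{0.01, 0.05, 0.1, 0.2, 0.3, 0.4, 0.5, 1.0} the score of individual *i* is

    PGS_i(P_T) = Σ_{j ∈ clumped, p_j < P_T} β_j · d_ij / M_T,

the *average* per included SNP (M_T), not the raw sum — a deliberate
convention choice, since most scoring tools default to sums. Cutoffs use
strict inequality (`p < P_T`). Empty cutoffs are flagged, never evaluated
as 0/0.

**Association.** At each cutoff the score is z-scored and enters a logistic
model next to the covariates (age, sex, and any site indicators or
principal components supplied as columns). The score's contribution is
summarized by the incremental Nagelkerke pseudo-R²,

    R²_N = [1 − exp((2/n)(ℓ₀ − ℓ₁))] / [1 − exp((2/n) ℓ₀)],
    ΔR² = R²_N(full vs null) − R²_N(covariates-only vs null),

with ℓ₀ the intercept-only log-likelihood. Wald p-values of the score
coefficient are BH-adjusted across the scan; the FDR family is the set of
cutoffs within one trait × one outcome × one cohort, which is the
configuration that matches how a threshold series is reported in practice.
The optimal cutoff is the smallest raw p (ties to the smaller cutoff), and
samples are then grouped by the empirical quartiles of that score
(boundary ties to the lower quartile); a logistic model with Q2/Q3/Q4
indicators gives odds ratios against the lowest quartile with Wald 95%
intervals.

**Cross-trait combination.** For each variant shared by two summary-
statistic sets, signed Z-scores are recovered as z = sign(β)·Φ⁻¹(1 − p/2)
(p clamped to ≥ 1e-300 for numerical safety) after harmonizing the second
set's alleles to the first (strand complements allowed; A/T and C/G pairs
are assumed already removed by QC, as they are unresolvable). Two
statistics are computed under a working Z-correlation Σ:

* O'Brien: T = (1'Σ⁻¹z)/√(1'Σ⁻¹1), powerful for concordant effects;
* direct linear combination: T_w = w'z/√(w'Σw) maximized over
  w ∈ {(1,1),(1,−1)}/√2, which also captures opposed effects.

The combined p is the smaller of the two. This minimum is taken *without*
multiplicity correction — deliberately, to match the reporting convention
of the published analysis — and is therefore anti-conservative; under the
null with identity Σ the two statistics are independent (sum and difference
of independent normals), so the exceedance at α is 1 − (1−α)² ≈ 0.0975 at
α = 0.05. The calibration test suite measures and asserts this inflation
rather than hiding it. A variant is reported only if the combined p is
genome-wide significant (< 5×10⁻⁸) *and* both univariate p are < 0.05; the
dual filter is applied before locus collapsing (configurable). Significant
variants collapse to loci greedily by ascending combined p, linking any hit
with r² > 0.1 within ±500 kb of the lead; an r²-only locus rule needs a
finite search window in practice, and ±500 kb is the conventional choice. Nearest genes come from BED intervals (0-based half-open; variant
positions are 1-based and converted at the boundary), ties alphabetical,
with "intergenic" beyond 1 Mb.

Σ defaults to the identity because the SSRI cohorts and the personality
consortia are disjoint samples. `estimate_sigma` serves overlapping-sample
pairs: it correlates the two Z fields over variants null in both scans
(both p > 0.05), shrinks |r| < 2/√m to zero, and divides by the
truncated-normal variance factor v = 1 − 2cφ(c)/(2Φ(c) − 1) to undo the
attenuation introduced by restricting both margins to |z| < c.

## Quality control

Filters run in a fixed order (sample call rate ≥ 0.95; variant call rate
≥ 0.95; strand-ambiguous SNPs; indels; MAF; exact Hardy–Weinberg; post-
imputation MAF; INFO), with per-stage removal counts recorded. The end
state is order-invariant, but the counts are not, hence the fixed order.
Boundary semantics are intentionally asymmetric and follow the conventions
of the stages they mimic: the genotyping-era MAF bound excludes *at*
equality (MAF ≤ 0.01), while the post-imputation MAF (< 0.10) and INFO
(< 0.9) bounds exclude strictly below. The Hardy–Weinberg test is the
exact conditional test: given the minor-allele count, heterozygote-count
probabilities follow the recurrence
P(h+2)/P(h) = 4·hom_minor·hom_major/((h+1)(h+2)), and the two-sided p sums
all configurations no more likely than the observed one (no mid-p). It is
applied to hard calls obtained by rounding dosages, missing genotypes
excluded, on all samples (the cohorts are all patients; there is no
case/control split to respect). Sex-consistency and relatedness exclusions
are consumed as precomputed drop lists, since no X-chromosome or pedigree
data are in scope.

## The synthetic cohort generator

The generator exists because the patient-level cohorts are access-
controlled. It reproduces the statistical structure the pipeline consumes,
not the biology:

* **Genotypes.** Diallelic dosages in LD blocks via a Gaussian copula on
  haplotypes: per block, two latent equicorrelated normal vectors
  (correlation `within_block_rho`, default 0.8) are thresholded at each
  variant's allele-frequency quantile and summed. Defaults: 250 blocks of
  20 SNPs (5 000 variants) spread over 22 chromosomes, 100-kb blocks
  (inside the clumping window) separated by 400-kb gaps (effectively
  unlinked), MAF ~ U(0.1, 0.5) so the post-imputation MAF filter is mostly
  a no-op on clean data, INFO fixed at 1.0 (overridable per variant to
  exercise the INFO filter). Dosage r² is an attenuated function of the
  latent rho (thresholding loses correlation); the clumping stage only
  needs r² to be tunably high within blocks and ~1/n across.
* **Trait GWAS.** Standardized causal effects b ~ N(0, h²/n_causal) at
  n_causal random variants. Each variant's marginal standardized effect is
  the LD-weighted sum of causal effects using the panel's realized dosage
  correlations, so tagged non-causal variants carry attenuated signal as in
  real summary statistics; realized correlations below 4/√n_panel are
  zeroed, because at the discovery sample size such correlations are
  indistinguishable from zero and would otherwise leak spurious signal into
  every unlinked variant (the panel is orders of magnitude smaller than the
  discovery cohort it stands in for). Reported statistics are
  z = α√N + ε with ε ~ N(0,1), SE = 1/(sd_j√N), β = z·SE — i.e., marginal
  statistics at the stated discovery N without regenerating a
  quarter-million-sample cohort. Defaults n_causal = 50, h² = 0.15 on the
  5 000-variant panel: a scaled-down polygenic architecture in which most
  LD blocks are null, so the threshold series actually varies. Discovery
  sample sizes default to the published personality-GWAS Ns (260 861;
  170 911 for neuroticism).
* **Outcomes.** Bernoulli draws from a logistic liability
  α + β·s + Σγ_c x_c with s the standardized true score. The intercept is
  root-found (Brent, xtol 1e-4) so the mean outcome probability equals the
  target base rate exactly on the realized covariates; the slope β is
  bisected — with common random numbers across candidate values so the
  objective is monotone — until the Nagelkerke ΔR² re-estimated on the
  generated data is within 0.5 percentage points (bisection stop 1e-3) of
  the target. Unachievable targets (e.g., a constant score) raise a
  calibration error rather than silently under-delivering. Base rates
  default to the published pooled response (46.8%) and remission (26.7%)
  rates; ΔR² targets default to the reported ~1.5% (response) and ~2.8%
  (remission) anchors; age/sex distributions match the pooled cohort
  demographics (age ~ N(42.2, 14.5²), 64.3% female). Default covariate
  effects (age −0.01 per year, sex +0.15 log-odds) are small nuisance
  signals of plausible magnitude; the published analysis reports no
  covariate coefficients to match.
* **True score.** `simulate_cohort` drives outcomes with the
  dosage-weighted sum of nominally significant discovery betas, so the
  recoverable signal lives where threshold-series scoring looks for it.
  The constructed PGS tags rather than equals this score; recovered ΔR² is
  therefore attenuated relative to the generative target, as in real data.

What passing tests on this generator do *not* show: behavior under real
haplotype structure (long-range LD, MAF-LD coupling), allele-frequency
spectra with rare variants, imputation-error patterns (INFO < 1),
population stratification, relatedness, X-chromosome effects, or indels.
The generator emits unrelated samples of known sex by construction.

## Numerical choices

* Logistic fits use Newton/IRLS (statsmodels), convergence tol 1e-8, max
  100 iterations. Perfect or quasi separation surfaces as a
  `SeparationError` (non-convergence or |coef| > 1e3), never as silent
  runaway coefficients. Wald, not profile-likelihood, intervals.
* Nagelkerke R² is clipped to [0, 1]; nesting is asserted
  (ℓ_full ≥ ℓ_reduced − 1e-8); an all-0 or all-1 outcome returns 0.
* Clump removal uses r² ≥ threshold (boundary removed); p-ties break by
  position then id, for determinism. LD is computed in the target cohort
  itself, per cohort.
* Missing dosages are mean-imputed per variant before scoring and LD;
  the HWE test instead drops them.
* BH adjustment is the standard step-up; it is *not* idempotent on its own
  output (a two-element counterexample exists), so only monotonicity and
  adjusted ≥ raw are asserted as properties.
* p-values are clamped at 1e-300 before normal-quantile inversion.

## Problem sizes in the test suite

Tests run on scaled-down instances chosen to keep the suite fast while
leaving every assertion meaningful: the shared fixture cohort is 600
samples × 600 variants; calibration recovery uses n = 10 000 cohorts;
type-I calibration uses 2 000 outcome permutations and 20 000 null
variants; oracle equivalence covers 100 random clumping instances, all
Hardy–Weinberg configurations with ≤ 200 genotypes (via their conditional
heterozygote distributions), and 50 random logistic designs against a
generic optimizer (agreement < 1e-6 per coefficient).

## Known limitations

* Two-trait combination only; the weight set and types are written for
  pairs (the O'Brien/dLC algebra generalizes, the containers do not yet).
* In-sample LD only — no external reference panel, and no shrinkage or
  continuous-weight scoring methods.
* The exact weighting and Σ used by the original C++ implementation of the
  combined statistics are not published; with equal weights and identity Σ
  the recomputed combined p-values land near but not exactly on previously
  printed values (e.g. 3.7×10⁻⁸ vs 4.04×10⁻⁸ for the response ×
  conscientiousness lead SNP). Printed combined p-values are therefore
  treated as threshold anchors, not exact targets.
* One outcome and one timepoint per association run; longitudinal
  trajectories are out of scope.
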