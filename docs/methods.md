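# Methods

This note documents the statistical procedures the package implements,
the choices made where the methodology is genuinely open, and what the
simulation-based tests do and do not establish.

## Gene-level methylation scoring

A 450k-style methylation array reports a beta value (a methylation
proportion in [0, 1]) per CpG probe, with several probes per gene split
between the promoter and the gene body. The package's gene-level
summary contrasts the two regions within one gene and one sample with a
two-sample t-form statistic:

    score = (x̄ − ȳ) / (Sw · sqrt(1/m + 1/n))
    Sw    = sqrt( [(m−1)S₁² + (n−1)S₂²] / (m + n − 2) )

where x̄, S₁² are the mean and variance of the m body-probe betas, and
ȳ, S₂² those of the n promoter probes. Under within-gene normal probe
noise and no regional difference the score follows t(m+n−2). The score
collapses a gene's probes to one number per gene per sample, so the
downstream two-group comparison operates on genes rather than probes.

Numerical choices:

* **Pooled-SD denominator.** The pooled variance uses the conventional
  denominator m+n−2, which is the only choice consistent with the
  declared t(m+n−2) reference, and the square root is applied so that
  the denominator of the score is a standard deviation. A historical
  variant with denominator m+n+1 circulates in some descriptions of
  this score; it is available behind `sw_denominator="printed"` for
  comparison, and is not used anywhere else.
* **Eligibility.** Both variance terms need two observations, so a gene
  is scored only if it has ≥2 promoter and ≥2 body probes. Missing
  betas are dropped per sample; the effective m and n for that sample
  enter both the pooled variance and the 1/m+1/n factor, and a sample
  whose effective count drops below 2 in either region is left unscored
  (NaN) rather than scored with a degenerate variance.
* **Degenerate cells.** Sw = 0 with equal region means yields score 0;
  Sw = 0 with unequal means is non-finite, set to NaN and counted in a
  warning.

## Differential screens

Two screens run in parallel and their significant gene lists are
intersected:

1. **Score-level screen.** Per gene, a two-sample t-test of the scores
   between control and treated samples, significant at p < 0.05.
   Welch's form is the default because it is safe under unequal group
   sizes and variances; the pooled test is available via `equal_var`.
   The score distribution has heavier-than-normal tails when m+n−2 is
   small, which makes the t-test mildly conservative; the null
   simulation below shows the realised size stays within a percentage
   point of nominal at the default probe counts.
2. **Probe-level screen.** Per probe, a linear model on the group
   indicator. For a two-level factor this is exactly the squared pooled
   two-sample t, reported as an F(1, N−2) statistic, and is computed
   vectorised across probes. p-values are converted to q-values by
   Benjamini–Hochberg step-up (delegated to
   `statsmodels.stats.multitest.multipletests`) and screened at
   q < 0.001. BH was chosen over Storey's estimator because it is
   deterministic and equals Storey with π₀ = 1; a Storey option is
   deliberately out of scope. Significant probes are collapsed to
   unique gene symbols via the annotation.

## Two-sample Mendelian randomization

Instruments are SNPs associated with the exposure at p < 5×10⁻⁸
(strict "less than"). Exposure and outcome summary statistics are
harmonized so both effects refer to the same effect allele: swapped
alleles flip the outcome beta and complement its frequency; strand
complements are matched before declaring a mismatch; palindromic (A/T,
C/G) SNPs are oriented by effect-allele frequency when both frequencies
are outside 0.5 ± 0.08 and excluded as ambiguous otherwise. Exclusions
carry machine-readable reason codes because downstream counts are
sensitive to them.

Per-SNP causal estimates are Wald ratios β_out/β_exp with first-order
SEs se_out/|β_exp|. Combination methods, all authored here:

* **IVW** — inverse-variance-weighted mean of ratios with weights
  w_j = β_exp,j²/se_out,j², algebraically identical to weighted
  regression through the origin (asserted to 1e-10 in tests). The
  default multiplicative random-effects SE inflates the fixed-effect SE
  by max(1, sqrt(Q/(J−1))), so it never undercuts it; the fixed model
  is a flag. Normal reference for p.
* **Weighted median** — interpolated weighted median of ratios,
  consistent while ≥50% of weight comes from valid instruments. Its SE
  comes from a parametric bootstrap (resampling both betas from normal
  distributions at their reported SEs) with an explicit seed and
  n_boot (default 1000).
* **MR-Egger** — weighted least squares of β_out on β_exp with a free
  intercept, after orienting every pair to β_exp ≥ 0 (Egger is not
  orientation-invariant; this is the published convention). The
  intercept estimates average directional pleiotropy; its two-sided
  t(J−2) p-value implements the decision rule that p > 0.05 means
  pleiotropy can be ignored. Both SEs carry the residual scale factor
  max(1, sqrt(Q_egger/(J−2))). Slope consistency requires InSIDE
  (pleiotropy independent of instrument strength).

Diagnostics: Cochran's Q about the IVW estimate (χ²_{J−1}) and
leave-one-out IVW re-estimation per instrument. Estimates are also
reported as odds ratios exp(β) with 95% Wald intervals; OR < 1 reads as
risk reduction per SD increase of the exposure.

**Two-step mediation.** Step 1 estimates exposure → mediator, step 2
mediator → outcome, each with the full suite. The mediated effect is
the product of the two IVW slopes; an optional delta-method SE
(sqrt(β₁²se₂² + β₂²se₁²)) treats the steps as independent. Any step
whose Egger intercept p ≤ 0.05 is flagged. No formal test of the
mediated effect is attempted beyond this.

**Known limitations.** No LD clumping or proxy lookup: instruments are
assumed independent, which holds for the simulator and must be ensured
upstream for real data. No Steiger filtering, MR-PRESSO or
multivariable MR. First-order Wald SEs ignore exposure-side noise,
which is negligible only when instruments are strong (see below).

## Synthetic data

The simulators exist so every stage is testable with known ground
truth; their defaults define the conditions under which the package's
statistical guarantees are demonstrated.

**Methylation cohort.** Two groups of 179 control and 190 treated
samples by default, matching the cohort shape this pipeline is built
around; per gene, 2–8 probes per region. Promoter baselines are drawn
at logit −2 (≈0.12 beta) and body baselines at logit +1 (≈0.73),
reproducing the canonical hypomethylated-promoter/methylated-body
pattern; gene-to-gene SD 0.5 on the logit scale. Probe-by-sample noise
(SD 0.5, logit scale) is added and mapped through the inverse logit,
which keeps betas strictly inside (0, 1) without clipping artifacts.
Effect genes receive a logit-scale shift on body probes of treated
samples only. What this generator does **not** emulate: probe-level
fixed offsets, spatial correlation along the array, cell-type
composition, batch effects, or beta-value heteroscedasticity near the
boundaries. Passing tests therefore demonstrate correctness of the
statistics, not robustness to array artifacts.

**GWAS pairs.** True instrument effects γ_j ~ N(0.15, 0.07); exposure
GWAS of 500,000 samples and outcome GWAS of 50,000; SEs follow
1/sqrt(2N·maf(1−maf)) with MAF ~ U(0.05, 0.5); observed betas are true
betas plus normal noise at those SEs, p-values from the normal
reference. Outcome effects are θγ_j + α_j + e_j with per-SNP pleiotropy
α_j ~ N(pleiotropy_mean, pleiotropy_sd) applied to a configurable
fraction of instruments (`frac_pleiotropic`), independent of γ by
default (InSIDE holds); `correlated_pleiotropy` ties α to γ to
demonstrate Egger's failure mode. Defaults were set so that all
instruments are unambiguously genome-wide significant with I²_GX ≈
0.99 — the strong-instrument regime in which the IVW and Egger
guarantees quoted below actually hold. At weaker settings (which the
config permits) Egger's intercept test over-rejects through regression
dilution; that behavior is inherent to the estimator, not to this
implementation. A configurable fraction of SNPs is palindromic (10% by
default) with the effect-allele frequency side shared between tables,
as it is for a real variant. No LD between SNPs is simulated.

**Triplets.** Two linked pairs through a mediator, with disjoint rsID
prefixes for the two instrument sets. The outcome table contains only
the mediator's instruments; exposure instruments that happen to reach
significance in the mediator table drop out harmlessly at the step-2
harmonization join, mimicking non-overlapping SNP coverage.

All generators are pure functions of their config (seed included):
identical configs give byte-identical outputs.

## Simulation scales and measured behavior

The statistical checks use these problem sizes, chosen to give
Monte-Carlo standard errors comfortably below the asserted margins:
2000 genes at 20+20 samples for null calibration of the screens; 200
replicates of a 60-gene, 50+50 cohort with 5 planted genes (logit
effect 1.0) for recovery through the intersection; 500 replicates of
J = 50 instruments for IVW recovery/coverage and Egger size/power; 200
replicates with 40% invalid instruments for weighted-median
robustness; 500 replicates for the mediation null. Coverage and size
are checked with the fixed-effect IVW SE because the simulated data
are homogeneous — the matched analysis; the random-effects default is
deliberately conservative there (it can only widen intervals). The
Egger intercept test is likewise slightly conservative (realised size
≈0.03–0.04) because of the max(1, ·) truncation of the residual scale,
the standard convention.

## Interfaces

All I/O is TSV with headers (beta matrix, probe annotation, sample
groups, GWAS summary tables); floats are written at round-trip
precision. Every pipeline run writes a JSON manifest with the config
echo, package and dependency versions, SHA-256 checksums of inputs and
all warnings, sufficient to re-run deterministic stages bit-identically.
The `simpomr` CLI (subcommands `methyl`, `mr`, `simulate`) is a thin
wrapper over the library; exit code 0 covers empty-but-valid results,
1 validation errors, 2 computational errors.
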