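# Methods

This note documents the statistical model behind `tsmr`, the defaults
and why they were chosen, what the synthetic-data generator does and
does not emulate, and the numerical conventions. It states no result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Data model and harmonization

A GWAS summary table holds one row per biallelic SNP: rsID, effect and
other allele, effect-allele frequency (EAF, optional), additive
per-allele effect estimate, its SE, p-value and sample size. Effects on
a quantitative trait are in SD units; on a binary trait, log-odds.
Indels and multi-allelic variants are rejected at parse time; duplicate
rsIDs are an input error. Matching between tables is by rsID only — the
intended data sources are rsID-keyed summary files, not positional VCFs.

Harmonization orients every outcome (and mediator) row onto the
exposure's allele pair: identical alleles are copied; swapped alleles
negate the beta; if the pair matches only after complementing both
outcome alleles (A↔T, C↔G), the row is strand-flipped first and the
same rule applied; anything else is dropped as unmatched and reported.
Palindromic SNPs (A/T, C/G) are dropped outright by default, because
their strand cannot be verified across cohorts from the alleles alone;
frequency-based rescue is deliberately not attempted (EAF is therefore
never load-bearing). When an exposure SNP is absent from the outcome
table, a proxy with r² > 0.8 (best r² first) may be substituted from a
user-supplied proxy table whose allele-correspondence column maps the
proxy's alleles onto the target's; the substituted instrument records
`proxy_of`. Every drop is counted and reasoned in a machine-readable
report, and the counts telescope exactly:
`n_input = retained + palindromic + unmatched`.

## Instrument selection

Selection applies, in order: genome-wide significance (strictly
p < 5×10⁻⁸), greedy LD clumping, harmonization (palindrome drop, proxy
substitution), and the weak-instrument filter F = (β/SE)² > 10. The
clumping rule visits SNPs by ascending p-value (lexicographic rsID as a
deterministic tie-break, so output is independent of input order) and
accepts a SNP iff its r² with every already-accepted SNP is ≤ the
cutoff (default 0.001). LD is consumed from a user-supplied sparse pair
table or square matrix — there is no network dependency; absent pairs
mean r² = 0. F is the standard summary-statistic approximation; the
test suite checks it against the regression F = (n−2)R²/(1−R²) on
simulated individual-level genotypes. The F filter runs after
harmonization and proxy substitution so the selection report describes
the final instrument set; the stage at which each SNP left the pipeline
is always recoverable from the report.

## Estimators

With harmonized effects (γ̂ⱼ, σ_xⱼ; Γ̂ⱼ, σ_yⱼ):

* **Wald ratio** β̂ⱼ = Γ̂ⱼ/γ̂ⱼ. Default SE is the first-order delta
  method σ_yⱼ/|γ̂ⱼ|; the second-order form
  √(σ_yⱼ²/γ̂ⱼ² + Γ̂ⱼ²σ_xⱼ²/γ̂ⱼ⁴) is available by flag and is verified
  against the Monte-Carlo SD of ratio draws.
* **IVW** is the inverse-variance-weighted mean of the ratios with
  first-order weights, identical to WLS of Γ̂ on γ̂ through the origin
  with weights σ_yⱼ⁻². `model="fixed"` uses SE = (Σwⱼ)^{−1/2};
  `"random"` multiplies by √max(1, Q/(J−1)) (multiplicative
  overdispersion); the default `"auto"` takes random effects when J > 3,
  else fixed — the prevailing two-sample practice when method variants
  are unstated. p-values are normal.
* **MR-Egger** is the same WLS with a free intercept, after orienting
  all γ̂ⱼ ≥ 0 (flipping Γ̂ with them) — the orientation under which a
  directional-pleiotropy intercept is meaningful; the flip is applied
  only inside this estimator. Coefficient covariances carry the
  √max(1, RSS/(J−2)) overdispersion factor and p-values use t with J−2
  df. The intercept block doubles as the directional-pleiotropy test,
  declaring "no directional pleiotropy" iff its p > 0.05.
* **Median estimators** interpolate the ordered ratios at cumulative
  standardized weight 1/2, with equal weights (simple) or normalized
  inverse ratio variances (weighted). SEs come from a parametric
  bootstrap (γ̂ⱼ*, Γ̂ⱼ* resampled from their reported normals; default
  1,000 draws; an explicit seed is mandatory).
* **Mode estimators** maximize a normal-kernel density over the ratios,
  with equal or inverse-variance kernel weights, bandwidth
  φ·0.9·min(SD, MAD)·J^{−1/5} (φ = 1 by default, exposed as
  configuration); the argmax is located on a 512-point grid and refined
  by bounded scalar minimization with tolerance tied to the grid step,
  so the estimate is invariant under rescaling of the outcome. SE by
  the same parametric bootstrap.
* **Maximum likelihood** maximizes the joint normal likelihood
  γ̂ⱼ ~ N(γⱼ, σ_xⱼ²), Γ̂ⱼ ~ N(βγⱼ, σ_yⱼ²). The latent γⱼ are profiled
  out in closed form, leaving a 1-D profile deviance
  Σ(Γ̂ⱼ−βγ̂ⱼ)²/(σ_yⱼ²+β²σ_xⱼ²) minimized deterministically from the
  fixed-effects IVW start; the SE is the inverse square root of the
  numerical profile curvature.

`estimate_all` runs all seven methods, skipping (with a recorded
reason, never aborting) any whose preconditions fail — Egger, medians
and modes need ≥ 3 instruments, ML ≥ 2. Every estimate carries β, SE,
95% CI, p, and the exponentiated odds-ratio scale.

## MR-PRESSO

The global test computes the observed RSS as the sum of each SNP's
weighted squared residual about its *leave-one-out* IVW prediction,
then simulates the null n_sim times by redrawing γ̂ⱼ* and Γ̂ⱼ* from
normals centered on the leave-one-out fitted values and recomputing the
RSS identically. The outlier test compares each SNP's observed squared
residual with its own simulated distribution, Bonferroni-adjusting
across J; the distortion test refers the shift between full and
outlier-corrected IVW estimates to a null built by removing equally
many SNPs at random. All empirical p-values use (r+1)/(n+1), so no
p-value is ever exactly zero, and the corrected estimate is exactly IVW
on the non-outlier subset. Defaults: n_sim = 1,000, outlier threshold
0.05 (Bonferroni), per the method's original publication. Note a
resolution constraint inherent to the Bonferroni form: flagging is
possible only when (1/(n_sim+1))·J < threshold, so J = 50 SNPs require
n_sim ≥ 1,000; the outlier-power validation experiment uses
n_sim = 2,000 to leave resolution margin.

## Multivariable MR and mediation

Multivariable IVW regresses Γ̂ on (γ̂_exposure, γ̂_mediator) jointly,
no intercept, weights σ_yⱼ⁻², with the same multiplicative
overdispersion scaling; a condition-number guard rejects collinear
designs. The default instrument set is the exposure's selected
instruments with mediator associations looked up in the mediator table
(SNPs missing there are dropped and reported); a union-of-instruments
mode is a caller choice, since either convention is defensible when
unstated. Mediation uses the difference method exactly:
indirect = total − direct (total from univariable IVW on the same
instruments, direct from the multivariable fit), proportion mediated =
indirect/total (undefined at total = 0, reported as such), and percent
risk forms (exp β − 1)×100 applied to points and CI bounds. The
proportion mediated is reported as a point estimate without a CI;
product-of-coefficients decomposition is out of scope.

## Power

Binary-outcome power uses the non-centrality normal approximation:
μ = |ln OR|·√(n·R²_xz·K(1−K)), power = Φ(−z_{1−α/2}+μ) + Φ(−z_{1−α/2}−μ).
It equals α exactly at OR = 1, is symmetric in OR ↔ 1/OR, and is
monotone in n, R²_xz and |ln OR| — all verified in tests. When R²_xz is
not supplied, the pipeline estimates it from the instruments as
Σ 2·EAF(1−EAF)·γ̂² (MAF 0.3 assumed where EAF is missing).

## Synthetic data

The generator emulates the *shape* of the motivating study's inputs: a
quantitative exposure GWAS of n = 321,223, a binary-outcome GWAS of
n = 1,030,836 with case fraction 60,620/1,030,836 ≈ 0.0588, and
optionally a 700,000-person mediator GWAS. Per SNP it draws MAF ~
U(0.1, 0.5), a true per-allele exposure effect |γⱼ| ~ U(0.015, 0.06) SD
(the magnitude of genome-wide-significant birth-weight loci), an
optional pleiotropic effect αⱼ (balanced or directional; an
"invalid" minority can carry large directional pleiotropy,
αⱼ ~ N(0.05, 0.01) by default), and an optional mediator path
mⱼ = θ_xm γⱼ + qⱼ with Γⱼ = β_direct γⱼ + θ_mo mⱼ + αⱼ. Defaults
θ_xm = 0.17, θ_mo = 0.53 and β_direct chosen so the implied total
effect sits at the OR ≈ 1.27 scale of the motivating analysis.
Observed estimates add normal noise with SE = (2·MAF(1−MAF)·n)^{−1/2},
binary traits scaling additionally by (K(1−K))^{−1/2}. αⱼ is drawn
independently of γⱼ, so InSIDE holds by construction. LD blocks assign
tag SNPs r² with their lead and attenuate tag effects by √r²; allele
pairs can include a requested palindromic fraction, and outcome/mediator
rows are randomly re-oriented (swap/strand-flip) to exercise
harmonization. All randomness flows from one explicit seed.

`paper_shape_fixture` composes a deterministic selection scenario: 146
independent lead SNPs (144 non-palindromic + 2 palindromic) and 83 tags
(r² = 0.8, z attenuated to 0.93 of their lead so clumping keeps the
lead), plus 20 sub-threshold SNPs — so the pipeline sheds SNPs
229 → 146 → 144 by construction, with all survivors at F > 10.

What the generator does *not* emulate: sampling correlation between
effect estimates of SNPs in LD (LD affects selection only), sample
overlap between the two GWASs, allele-frequency–dependent effect-size
architecture, population stratification, and binary-trait
noncollapsibility. Passing tests therefore demonstrate correctness of
the estimators and pipeline under the stated model, not robustness to
those real-data features.

## Validation experiments

`tsmr.calibration` fixes the simulation designs used by the test suite
and the acceptance script. Every replicate draws a fresh study (MAFs,
SEs, true effects) so measured rates average over study configurations
rather than conditioning on one draw:

* IVW recovery: J = 144, true β = 0.233, study-scale SEs — mean bias
  and 95% CI coverage over 1,000 replicates.
* Type-I error: β = 0 with balanced pleiotropy αⱼ ~ N(0, 0.005) — a
  level that roughly doubles the outcome-side variance of precise SNPs,
  comparable to the heterogeneity the overdispersion factor is meant to
  absorb. The Egger intercept test is mildly anti-conservative here
  (constant pleiotropy variance makes σ_y⁻² weights misspecified), so
  the suite measures the rate at 3,000 replicates to keep Monte-Carlo
  error small against the acceptance band.
* Robustness: 30% of 50 instruments invalid with directional
  pleiotropy (0.05 mean), exposure effects oriented positive — the
  orientation under which directional pleiotropy accumulates instead of
  cancelling; bias of weighted median vs IVW over 200 replicates.
* MR-PRESSO: detection rate for a planted 5-outcome-SE outlier among
  50 SNPs over 100 runs, and KS uniformity of the null global p over
  200 runs (n_sim = 300, ample resolution for a uniformity check).

## Numerical conventions and degenerate inputs

Zero exposure beta makes a Wald ratio undefined and is an error;
p-values are floored at 10⁻³⁰⁰ in the generator to respect the (0, 1]
domain; the mode estimator returns the weighted mean when the ratio
spread is exactly zero (degenerate density); ML reports
non-convergence and non-positive curvature explicitly instead of
returning garbage; empirical p-values are never zero by construction.
Ties in clumping are broken lexicographically. Bootstrap and simulation
routines require explicit seeds — there is no hidden global state, and
identical seeds give bit-identical results.

## Known limitations

Correlated instruments (generalized IVW), robust/penalized IVW,
MVMR-Egger, Steiger filtering, CAUSE-type methods, sample-overlap
correction and non-linear or sex-stratified analyses are out of scope.
The LD interface consumes user-supplied r² values; it does not estimate
LD from a reference panel. The mediation CI covers only the total and
direct effects, not the proportion mediated.
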