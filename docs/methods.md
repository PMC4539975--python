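# Methods

## Data model and conventions

Every test operates on a single marker's 2×3 genotype table: counts
(r₀, r₁, r₂) for genotypes AA/AB/BB in r cases and (s₀, s₁, s₂) in s
controls, pooled genotype totals nᵢ = rᵢ + sᵢ, n = r + s.  Conventions used
throughout:

* z statistics are signed so that positive means allele B over-represented
  in cases (HWDTT: excess homozygosity in cases);
* two-sided p-values are 2(1 − Φ(|z|)); sign(0) ≡ +1 wherever a direction
  is recorded; no continuity corrections (all tests are asymptotic);
* a table is *degenerate* when the relevant score has zero variance
  (e.g. monomorphic); degenerate tables raise `DegenerateTableError`, and the
  CLI reports such markers as NA rows instead of aborting a batch;
* Pearson's test drops genotype classes absent from the pooled sample and
  reduces the degrees of freedom to (#nonempty − 1), since their terms are
  0/0 and the asymptotic df collapses.

## Null correlations and a rank-2 identity

The two-phase p-values need the null correlations among (Z₀, Z_½, Z₁, Z_H).
Trend-test pairs use the closed-form multinomial covariance of the score
vectors at the pooled frequencies nᵢ/n; trend-vs-HWDTT correlations
linearise the HWD coefficient Δ̂ = p̂₂ − (p̂₂ + p̂₁/2)² (delta method,
influence vector (0, −θ, 1−2θ) at the pooled allele frequency θ).  The
plug-in estimates are validated in the test suite against a parametric
bootstrap of 120 000 null tables.

All four statistics are standardised case-minus-control contrasts of three
genotype proportions, so they span a Gaussian space of rank two: the 4×4
correlation matrix is always singular, and conditional on Z_H the pair
(Z_x, Z_½) is perfectly correlated.  Numerically this makes the conditional
orthant probabilities piecewise (a kink where the two conditional thresholds
cross); the fixed-order quadrature panels are split at the kink, which
restores fast convergence.

## Selection-adjusted p-values

**MIN2.**  Under the null the Pearson statistic decomposes as
T = Z_½² + W with W an independent χ²₁.  With a = H₁⁻¹(1−m) and
b = −2 log m (the χ²₂ quantile), the adjusted p-value is

    P(MIN2 ≤ m) = 2m − S₁(b) − ∫ₐᵇ h₁(v) S₁(b−v) dv  ∈ [m, 2m],

evaluated by adaptive quadrature (absolute tolerance 1e-10) in the scalar
path and by 64-point Gauss-Legendre in the vectorised path (the integrand's
√v singularity only matters for m near 1, where only the selection decision
— never a reported p-value — uses the batch result).

**GMS / GME.**  The p-value is the survival function of the *oriented*
two-phase statistic: the sum over the recessive and dominant selection
regions of trivariate-normal orthant probabilities plus the additive-band
term, each doubled because the two risk-allele branches (sign of Z_½) are
equiprobable and symmetric under global negation.  Orthant terms reduce to a
one-dimensional integral over Z_H of closed-form bivariate-normal orthants;
the bivariate CDF itself is evaluated exactly through Owen's T function
(machine precision, deterministic, vectorised) rather than through a
Monte-Carlo multivariate-normal CDF, because reported p-values down to 1e-7
must carry several accurate digits and simulation-scale batches need
millions of evaluations.  Infinite limits are truncated at |z| = 8.5
(excluded mass < 1e-16).  The scalar path uses adaptive quadrature
(tolerance 1e-9); the batch path uses kink-split 48-point Gauss-Legendre
panels; both agree to ~1e-6 or better and match Monte-Carlo oracles of the
asymptotic null (2×10⁶ draws) within 3 standard errors.  GME reuses the GMS
machinery after mapping the correlations to those of the hedged statistics
Z*_x, which are unit-variance by construction.

**MAX3.**  The bootstrap p-value draws case/control tables from multinomials
at the pooled frequencies (default B = 100 000, add-one estimator,
deterministic given the seed).  The asymptotic mode — used inside
simulations, where a per-table bootstrap would be prohibitive — integrates
the rank-2 trivariate normal box probability by the same conditional-orthant
quadrature.

## Replication stage

The stage-2 p-value is one-sided in the discovery direction:
P_x⁽²⁾ = 1 − Φ(sign(Z_x⁽¹⁾) Z_x⁽²⁾) for the score x chosen at stage 1
(MAX3: the score with the smallest stage-1 single-model p-value; MIN2: the
additive branch iff P_½⁽¹⁾ ≤ P_χ²⁽¹⁾, ties to additive, comparing the two
*stage-1* p-values; GMS/GME: the stage-1 Z_H region with recessive/dominant
roles exchanged when Z_½⁽¹⁾ ≤ 0).  GME restandardises the stage-2 starred
statistic with correlations estimated from the stage-2 table, so each
stage's statistic is standard normal under its own sampling.  Stage-1
records can be rebuilt from stage-1 counts at any time and are pure
functions of the table.

## Conditional combined tests

Selection at stage 1 (P⁽¹⁾ < α_D) must be conditioned on.  The Fisher
combination has closed forms (natural logarithms; the equal-weight branch is
used when |w₁−w₂| < 1e-9, where the unequal-weight form is singular); its
support starts at z = −2w₁ ln α_D, where the p-value equals α_D.  The
inverse-normal combination's conditional probability is a one-dimensional
normal integral from z_{1−α_D/2}.

The published LC integrand carries the standard-normal density φ for the
discovery probit, but Φ⁻¹(1 − P⁽¹⁾/2) of a two-sided uniform p-value is
*half*-normal (density 2φ on z > 0), so the printed expression equals
exactly half of P(P⁽¹⁾ < α_D, Z_LC > z).  `lc_pvalue` evaluates the printed
form by default (ceiling α_D/2) and the exact conditional probability with
`exact=True`; Monte-Carlo oracles in the test suite confirm the factor of
two, and all internal calibration (the LC rejection threshold used by the
simulator) uses the exact form — the published type-I-error tables are only
reproducible that way.  Critical values for both combinations are obtained
by bracketing root finds on the (strictly monotone) conditional p-values to
1e-12.

## Simulator

A marker is parametrised by MAF p, inbreeding coefficient F
(g₂ = p² + Fp(1−p), implied HWD coefficient Δ = Fp(1−p)), prevalence K and
genotype relative risks λ₁ = f₁/f₀, λ₂ = f₂/f₀ constrained by the genetic
model (REC λ₁=1, ADD λ₁=(1+λ₂)/2, MUL λ₁=√λ₂, DOM λ₁=λ₂).  Penetrances are
solved from Σfᵢgᵢ = K and inverted by Bayes' rule into case/control
genotype distributions; each stage's tables are independent multinomials
with stage sizes round(π_s·n) and the remainder.  Between-stage effect
heterogeneity re-solves the penetrances per stage at the same MAF and K.

Default scenario values mirror the type-I-error study: K = 0.1, MAF 0.3,
F = 0, 1500 cases + 1500 controls split π_s = 0.5, M = 10 independent
markers, genome-wide α = 0.05 with Bonferroni (per-marker level α/M),
α_D = 0.05, α_H = 0.05, 20 000 replicates; power runs use 1000+1000 samples
and 2000 replicates.  Strategies evaluated per test:

* REP: reject if P⁽¹⁾ < α_D and P⁽²⁾ < (α/M)/α_D.  The stage-2 level is not
  published; because the stages are independent under the null, this product
  rule is the unique choice whose per-marker type I error is exactly α/M for
  every α_D, and it reproduces the published table's ≈0.005 rates.
* FC / LC: reject if P⁽¹⁾ < α_D and the combination statistic exceeds the
  critical value solving its conditional p-value = α/M (exact LC form).

Randomness: replicate r uses `numpy`'s `default_rng((seed, r))`, markers
drawn sequentially within the replicate — reproducible and parallelisable by
replicate.  The engine computes every statistic as vectorised array kernels
shared with the single-table API; MAX3 uses the asymptotic p-value and
GMS/GME the Gauss-Legendre batch quadrature.  Simulated robust tests are run
at 20 000 replicates for CATT/Pearson/MIN2 and 5 000 for MAX3/GMS/GME in the
test suite, sizes at which every binomial 3-SE check is decisive while the
suite stays fast.

## What the simulator does and does not emulate

It emulates exactly the sampling model of the published experiments:
independent markers, multinomial genotype draws within fixed case/control
totals per stage, no linkage disequilibrium, no population stratification,
no covariates, and the same parametric family for effects.  Passing
calibration and power checks therefore demonstrates correctness of the
statistics under that model — not robustness to LD, stratification,
genotyping error or case-control imbalance drift between stages, which real
data exhibit and which are out of scope here.

## Numerical and design notes

* The HWDTT variance (p̄q̄)² is derived under HWE; off HWE the statistic is
  mildly miscalibrated (≈0.054 at level 0.05 for a markedly off-HWE marker)
  — a property of the published statistic, relevant only to its use as a
  stand-alone test, not to model selection under the F = 0 study conditions.
* MAX3 argmax ties break in recessive, additive, dominant order; MIN2
  component ties go to the additive branch.
* Stage-1 selection uses strict inequalities exactly as stated
  (Z_½ > 0 vs ≤ 0; Z_H > c / < −c).
* Degenerate tables inside a simulation batch yield NaN p-values and are
  never selected or rejected (conservative; they cannot occur at the default
  MAF/sample sizes in practice).
* KS-based uniformity/independence checks of stage p-values use large
  per-group sizes (8000), because at a few hundred observations per group the
  discreteness of genotype counts alone is detectable by a KS test with
  20 000 samples — a finite-sample artefact, not a failure of the asymptotic
  independence argument.

## Known limitations

Asymptotic p-values throughout (no exact small-sample tests, no genomic
control); two stages only; no covariate adjustment, imputation, LD or
X-chromosome handling; the ABT is reported but its normal calibration
requires HWE, as documented.
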