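# Methods

## Model ensemble

All models describe two independent groups of real-valued observations.
Group g ∈ {1, 2} has location μ_g and scale σ_g, parametrized through a
common vector (μ, σ, δ, ρ, ν):

* μ_g = μ ∓ δσ/2 (minus for group 1), so the mean difference is
  MD = μ₂ − μ₁ = δσ and δ is Cohen's δ;
* σ₁² = 2σ²(1 − ρ), σ₂² = 2σ²ρ, so σ₁² + σ₂² = 2σ² (the grand scale is
  the variance average) and ρ is group 1's share of the total
  precision: ρ = (1/σ₁²)/(1/σ₁² + 1/σ₂²).  The standard deviation
  ratio is SDR = σ₁/σ₂ = √((1−ρ)/ρ); equal variances mean ρ = ½.
  The worked anchor: variances (2, 4) have precisions (½, ¼), hence
  ρ = ⅔ and SDR = √½.  A configuration switch (`sdr_convention`) flips
  the reported ratio to σ₂/σ₁ for users who prefer the reciprocal
  convention;
* the likelihood is normal, or Student-t with ν degrees of freedom and
  scale s_g = σ_g √((ν−2)/ν), so that the t likelihood's standard
  deviation is exactly σ_g for every ν > 2 and δ retains its meaning
  across likelihoods.

The eight ensemble members (RoMB) are all combinations of
effect ∈ {δ = 0, δ free}, variances ∈ {ρ = ½, ρ free}, and
likelihood ∈ {normal (ν = ∞), t (ν free)}.  The four normal-likelihood
members form the MB ensemble; the equal-variance normal pair is the
Bayesian Student test and the unequal-variance normal pair the Bayesian
Welch test.

## Priors

| parameter | default prior | notes |
|---|---|---|
| δ | Cauchy(0, 1/√2) | the standard default-test scale; location/scale and an optional truncation interval are configurable (e.g. Cauchy(0, 0.05) for a tightly informed test) |
| ρ | Beta(1.5, 1.5) | symmetric, mildly regularizing; places ≈90% prior mass on SDR ∈ [⅓, 3] |
| ν | 2 + Exponential(1) | prior mean 3, quartiles 2 − ln 0.75 ≈ 2.3 and 2 − ln 0.25 ≈ 3.4; the shift by 2 keeps the t likelihood's mean and variance finite, which the δ-parametrization requires; the mass near 2 keeps t models distinguishable from normal ones |
| μ, σ | p(μ, σ) ∝ 1/σ | Jeffreys, improper, shared by all models so the arbitrary constant cancels in every Bayes factor and all BFs are exactly invariant to affine data transforms |
| models | uniform | 1/2, 1/4, or 1/8 per member depending on the ensemble; configurable |

Prior model probabilities combine with marginal likelihoods through a
log-sum-exp-stabilized softmax; inclusion Bayes factors divide the
posterior odds of a model set by its prior odds, which makes them
invariant to the prior odds themselves.

## Marginal likelihoods

**Normal models (quadrature, summary statistics suffice).**  Given
(δ, ρ), write v₁ = 2(1−ρ), v₂ = 2ρ, k_g = n_g/v_g, K = k₁ + k₂,
k_h = k₁k₂/K, S = Σ_g (n_g − 1)s_g²/v_g, and the ρ-specific statistic
t_obs = (m₂ − m₁)√k_h / √(S/(N−2)).  Integrating (μ, σ) against the
Jeffreys prior gives, in closed form,

    p(y | δ, ρ) = p(y | 0, ρ) · f_nct(t_obs; N−2, δ√k_h) / f_t(t_obs; N−2),

where p(y | 0, ρ) is an inverse-gamma integral with an explicit
expression and f_nct is the noncentral-t density.  At ρ = ½ this is the
classic default-Bayes-factor construction (pooled t statistic,
effective sample size n₁n₂/N); the unequal-variance case only changes
the weights.  The remaining integral over the free members of (δ, ρ)
is computed after mapping each parameter through its prior quantile
function (so the prior becomes the uniform measure on (0,1)^d and the
heavy Cauchy tails are compactified), using nested Gauss–Legendre
rules whose order doubles until successive values agree to relative
tolerance 1e-8.

We evaluate the noncentral-t log density with an in-house routine
(integral representation, 96-point Gauss–Legendre around the mode of
the log-concave inner integrand) because scipy's implementation returns
NaN in a (large df, |ncp| ≳ 8) region these integrals visit routinely;
the routine agrees with scipy to ~1e-9 wherever scipy is finite and
with high-resolution direct integration to ~1e-13 elsewhere.

Posterior draws for normal models are obtained without MCMC: the
(δ, ρ) posterior is inverted on a fine grid in prior-CDF coordinates
(384² cells for two free parameters, 8192 for one), with uniform
jitter inside cells; given (δ, ρ), 1/σ has a known density
(t^{N−2}exp(−αt² + bt)) inverted on a grid, and μ | σ is exactly
Gaussian.

**t models (MCMC + bridge sampling, raw data required).**  The free
parameters are sampled on unconstrained scales
(μ, log σ, δ, logit ρ, log(ν−2)) with emcee's affine-invariant
ensemble sampler using differential-evolution moves (a 0.8/0.2 mixture
of DEMove and DESnookerMove, which mixes about three times faster than
the default stretch move on these 3–5 dimensional posteriors).
Defaults: 32 walkers, 1000 warmup steps, 750 kept steps (24,000 kept
draws).  Convergence is assessed by split-chain R̂ with walkers grouped
into eight super-chains; the strict flag threshold is 1.01, the run is
retried with doubled lengths up to three times, and failure raises an
error carrying the diagnostics.  Large simulation sweeps use a reduced
preset (16 walkers, 250 + 250 steps, R̂ gate 1.05) — the strict-1.01
flag is still recorded per fit.

The log marginal likelihood is estimated by the Meng–Wong optimal
bridge between (up to 4000 thinned) posterior draws and a
moment-matched multivariate-normal proposal, iterated in log space to
relative tolerance 1e-6 (cap 1000 iterations).  The standard error uses
the relative-mean-squared-error formula for the bridge estimator with
the posterior-side variance term inflated by N/ESS to account for
autocorrelated draws; against the brute-force oracle the reported SE is
mildly conservative (observed spread across seeds ≈ ⅓ of the reported
SE on the reference 4+4 dataset).

**Grid oracle (testing only).**  An independent tensor-product
Gauss–Legendre quadrature over *all* free parameters, including
(μ, σ): δ, ρ, ν map through their prior quantile functions; μ uses a
wide data-centred Student-t(4) proposal and σ a lognormal proposal,
with the importance ratio applied explicitly.  It is deterministic,
capped at ~1e8 grid nodes, intended for ≤ ~15 observations per group,
and validated by node-doubling self-convergence; the production
quadrature path matches it to ~1e-9 and the bridge path to well within
its Monte-Carlo error.

## Model-averaged inference

Posterior mixtures are sampled directly: choose a model in proportion
to its posterior probability, then draw the parameter from that model
(a spec-implied constant — δ = 0, ρ = ½, ν = ∞ — where it is fixed).
Default 10⁵ mixture draws; central 95% quantile intervals; the mean
summarizes δ and SDR, the median summarizes ν (computed on the extended
real line, so the median is ∞ whenever normal-likelihood models carry
more than half the mixture, with a finite lower interval bound).  Two
variants are always computed and labeled: the all-model mixture
("averaged") and the mixture restricted to models in which the
parameter is free with renormalized weights ("conditional").  The
conditional variant is how the ensemble reports effect sizes — the
all-model mixture deliberately shrinks toward the null point mass and
is the honest answer to a different question.

## Sequential and replication analysis

Sequential trajectories re-fit the chosen ensemble on growing data
prefixes (default: one new observation per group per checkpoint,
starting at 2+2); every checkpoint is a complete fresh analysis, so
there is no path dependence and the final checkpoint equals the
full-data fit.  Replication Bayes factors use the evidence-updating
quotient BF_rep = BF_combined / BF_original applied to each inclusion
Bayes factor, which implicitly updates both the parameter priors and
the prior model probabilities to the original study's posterior without
requiring density estimation of that posterior.

## Simulation harness

`simulate_condition` draws data with grand μ = 0, grand σ = 1: group
SDs from the target SDR under σ₁² + σ₂² = 2, means ∓δ/2, and either
normal or Student-t(ν) noise rescaled by √((ν−2)/ν) so the population
SD equals its target for every ν (keeping δ comparable across
likelihood conditions; `raw_t_scale=True` disables the rescaling for
sensitivity analyses).  Group sizes follow n₂ = round(total/(1+r)),
n₁ = total − n₂ for allocation ratio r = n₁:n₂ (e.g. total 50, r = 2 →
33/17).  Replicates are seeded by a (seed, condition-hash, rep)
seed-sequence, so results are independent of worker count and
individual failures are logged as missing rather than fatal.

Evidence distortion factors compare each test's BF₁₀ for the effect to
the test matching the generating process: normal data map to Student
(SDR = 1) or Welch (SDR ≠ 1); t-generated data map to the matching
single-model pair with a t likelihood (equal- or unequal-variance).
EDF of the matching test is identically 1.  Because EDFs are ratios,
per-condition summaries report geometric means and quantiles.

## Problem sizes used in the test suite

The suite runs the complete scientific checks at desk scale, chosen so
each check is decisive for its property: oracle comparisons use a fixed
4+4 dataset (the largest size at which the 5-D tensor grid is exact and
cheap); effect-size recovery uses 200 replicates of the
δ = 0.5 / SDR = 2 / t(5) / n = 50-per-group condition with the reduced
sampler preset; distortion checks use 100 replicates per condition.
The full 3⁵ × 1000 factorial is supported through the same
`run_study`/CLI path and produces the identical summary schema.

## What the synthetic conditions do and do not cover

The generator emulates symmetric heavy tails via scaled Student-t
noise.  Real outliers are often asymmetric, clustered, or generated by
mixtures; the t likelihood (and hence the ensemble) can absorb some of
this but is not a license to skip looking at the data.  Likert-type
ordinal data, bounded or skewed outcomes, and paired designs are
explicitly out of scope — passing tests here say nothing about those
settings.

## Known limitations and degenerate inputs

* Groups need at least two observations and nonzero variance; the
  robust ensemble needs raw data.
* The bridge SE is an approximation under correlated draws; tests use
  3·SE margins and the oracle cross-check rather than trusting it
  blindly.
* Inclusion Bayes factors can be numerically infinite when one model
  set's posterior mass underflows (reported as `inf` with a warning).
* With very small groups (n_g ≤ 3) the t-likelihood posterior on ν is
  close to its prior and the outlier inclusion BF is mostly
  prior-driven — expected behavior, not evidence.
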