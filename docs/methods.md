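# Methods

This note documents the statistical models implemented in `teres`, the
defaults and why they were chosen, the synthetic-data generator and what it
does and does not emulate, and the numerical decisions that matter for
reproducing results.

## Survival model and estimation

All residuals are computed from a parametric Weibull survival model,
S(t) = exp(−(t/λ)^k), with λ the scale in years and k the dimensionless
shape. The censored log-likelihood is

Σ_{events} log f(t_i; λ, k) + Σ_{censored} log S(t_i; λ, k),

maximized over (log λ, log k) (unconstrained, so positivity is automatic)
by BFGS with analytic gradients. Starting values come from a moment match
on the uncensored times only (k₀ = (s/m)^−1.086 from the coefficient of
variation, λ₀ = m / Γ(1 + 1/k₀)); convergence is declared when the
gradient of the *mean* log-likelihood falls below 1e−8 in norm, a
tolerance that is invariant to sample size. The observed-information
covariance (finite differences of the analytic gradient, delta method back
to the natural scale) is exposed for standard errors. Samples with no
events (likelihood unbounded) or zero variance among event times
(shape diverges) are rejected with explicit errors rather than returning a
spurious optimum.

With a categorical covariate, one Weibull is fitted per covariate level;
every downstream per-level quantity (median, conditional median,
cumulative hazard) uses that level's fit. An inclusion mask lets callers
restrict estimation to unrelated individuals while still computing
residuals for everyone — the estimation step assumes independent
observations, the residual evaluation does not.

A Kaplan–Meier estimator (delegating to lifelines, with the conventional
events-before-censorings tie rule) is provided purely as a goodness-of-fit
diagnostic for the Weibull choice.

## Residuals

For each individual, MR and DR are evaluated at the individual's own
observed time with its own event indicator. OTE (and the naive OLRR) are
evaluated at t\*: the failure time if uncensored, the conditional median
t_pred = λ[(t_cens/λ)^k + ln 2]^(1/k) if censored, with the constant
b = −log 0.5 in place of the event indicator. The OTE transform is
OTE = sign(b − x)·√(−2 g(x)) with x = CHF(t\*) and
g(x) = b − x − b log b + b log x, which is ≤ 0 with its maximum 0 at
x = b; setting b = 1 in g recovers the uncensored deviance residual
exactly, which the tests verify to 1e−12.

Numerical guards: the argument under the square root can be a tiny
negative number (order 1e−16) from roundoff and is clipped to zero below
1e−12 in magnitude; larger negative arguments raise. An evaluation time of
exactly zero (CHF = 0) is rejected — event times are strictly positive in
the data model — rather than mapped to an infinite residual.

Standardization subtracts the within-level mean and divides by the
within-level sample standard deviation (n − 1 denominator), per residual
kind, so that levels pool on a common scale. Zero within-level variance is
an error naming the offending level. MMR is exposed as its own residual
kind for testability even though it is only an intermediate of OTE.

A property worth knowing when interpreting OTE locations under censoring:
because every censored individual is assigned t_pred strictly above the
fitted median, the within-sample *median* of raw OTE is slightly negative
whenever censoring occurs below the median survival time — about −0.07 at
censoring proportions of 30–70% in the calibration study below — while the
*mean* stays within ±0.03 of zero. Both are an order of magnitude closer
to zero than the corresponding drift of the Martingale and deviance
residual medians (±0.25–0.37 over the same range), which is the sense in
which OTE's location is robust to the censoring mechanism.

## Synthetic cohorts

The generator emulates a modifier-gene study of a progressive disease with
one binary clinical covariate:

- **Genotypes**: one biallelic SNP, allele-1 frequency q = 0.5 by default,
  Hardy–Weinberg proportions (counts ~ Binomial(2, q)).
- **Event ages**: per genotype and covariate level, normal on the standard
  scale (the eight built-in model rows cover no effect, additive,
  inflated-variance, dominant, recessive, mean+variance, variance-only,
  and genotype-by-covariate patterns), mapped to years as
  `years = 11.6 + 3.4·z`, the location/scale of the motivating uncensored
  phenotype. Covariate level 2 adds 3 years (models 1–7); model 8 carries
  explicit level-2 means and s.d.s that already embed its covariate
  effect. Ages are left-truncated at zero by rejection sampling, which
  preserves a proper truncated-normal density (clamping would not).
- **Observation ages**: negative binomial with r = 10, p = 0.4 under the
  mean r(1−p)/p convention (mean 15 years). This convention is the one
  consistent with the design's ≈40% censoring; the alternative (mean ≈6.7)
  would censor most of the sample. Draws of exactly zero (probability
  ≈1e−4 at the defaults) are redrawn, since an individual censored at age
  zero carries no information and would violate the positive-time data
  model. Ages are integer-valued; no jitter is added, and ties between the
  continuous event ages and integer observation ages have probability
  zero.
- **Censoring**: an individual is uncensored iff their event age is
  strictly below their observation age; the recorded time is the minimum
  of the two (ties, were they possible, would censor).

Under the defaults this yields ≈42% censored at n = 50,000, and censored
Weibull fits at n = 10,000 with scale ≈12.7–12.9 years and shape
≈3.8–3.9 — i.e. the normal-mixture years scale is, as intended,
effectively Weibull (Kolmogorov distance between the fitted Weibull and
the Kaplan–Meier curve < 0.02 at n = 10,000).

The `censoring_robustness_study` helper varies the observation-age
parameters over r ∈ [2.5, 14.5], p ∈ [0.25, 0.35] (spanning censoring
proportions from ~0 to ~0.87), refits, and records fitted parameters and
raw residual locations per replicate; it reports *raw* residual means and
medians because the standardized versions are identically centred.

What the generator does **not** emulate: family structure (all individuals
are unrelated), linkage disequilibrium between markers, genome-scale
marker panels, time-dependent covariates, and informative censoring
(observation age is independent of event age). Conclusions from the test
suite therefore speak to the residual constructions and the estimation
machinery, not to robustness against those real-data complications.

## Simplified PPLD

The association score for a quantitative trait (a standardized residual)
against a 0/1/2 genotype is a Bayes ratio BR = ∫ LR(γ) f(γ) dγ over
γ = (μ₁₁, μ₁₂, μ₂₂, σ₁₁, σ₁₂, σ₂₂), the parameters of three
location-scale t distributions (df = 10 by default, configurable; t
kernels keep the score robust to non-normal traits). The likelihood ratio
shares γ between numerator and denominator: the numerator evaluates each
individual under their own genotype's t distribution; the no-association
denominator evaluates everyone under the genotype-frequency-weighted
mixture of the same three distributions (without association the marker
genotype carries no information about the trait component). Sharing γ
makes pure distribution-shape effects cancel, so BR rewards
trait–genotype dependence specifically — with a fixed pooled-t
denominator instead, heavily skewed residuals (e.g. MR, skewness ≈ −1.8
under 40% censoring) earn spuriously large scores. The SNP is modelled as
the trait locus itself (recombination fraction 0, D′ = 1, admixture 1,
trait allele frequency equal to the marker's), so genotype effects on
means and/or variances are captured directly.

The prior f(γ) is explicit and scale-adapted to the trait vector (sample
mean m, s.d. s): independent uniforms, means on [m − 3s, m + 3s], s.d.s on
(0.3s, 3s]. The integral is evaluated with 2^13 scrambled-Sobol nodes via
defensive mixture importance sampling — half the nodes map through the
uniform prior, half through a Gaussian proposal centred at the class-wise
sample moments (s.d.s 3σ̂_c/√n_c for means, 3σ̂_c/√(2n_c) for s.d.s), with
exact mixture-density weights. Plain (quasi-)Monte Carlo on the prior box
fails at realistic sample sizes: at n = 500 the posterior occupies a
~1e−9 fraction of the box volume, so no unguided node lands near the
peak and the integral is underestimated by many orders of magnitude. The
mixture estimator is unbiased for the same integral and reports a relative
Monte-Carlo standard error. The posterior probability
PPLD = πBR/(πBR + 1 − π) uses π = 0.0004 and is computed from log BR so
it saturates gracefully when BR overflows.

Monomorphic markers and genotype classes with fewer than two members are
rejected. This module is a deliberately simplified, unrelated-individuals
score: it is not numerically interchangeable with pedigree-likelihood
implementations of the PPLD, whose priors and trait-likelihood form
differ; within the package it serves to compare residual kinds under a
common, fully documented measure.

## Replicate experiments and problem sizes

`score_experiment` / `run_model_grid` simulate replicate cohorts
(default n = 500, half per covariate level), residualize, and score each
residual kind, reporting the mean and s.d. of the PPLD distribution and
the cross-kind correlations. Replicate counts default to 100 (library) and
50 (test suite) rather than the thousands a production study would use;
at 50 replicates the mean PPLDs of different residual kinds on the same
replicates are strongly correlated, so paired comparisons (OTE vs DR) are
much more stable than the ±0.05-ish standard errors of the individual
means suggest. The calibration study uses 100 replicates at n = 10,000;
the acceptance script uses n = 50,000 for the censoring fraction and
n = 10,000 for the Weibull fit.

## Known limitations

- Only the Weibull family ships as a survival model; the residual code
  accepts any object exposing `chf`, `median` and `predicted_median`
  (plus a generic bisection `conditional_median` for arbitrary survival
  functions), but no other family is provided or tested.
- One categorical covariate; no continuous covariates, interactions,
  time-dependent covariates, or frailty terms.
- The PPLD here is a single-marker, unrelated-individuals score; no
  pedigree likelihood, no sequential updating across data subsets, no
  multi-marker LD structure.
- Weibull estimation assumes non-informative censoring; the simulator
  satisfies this by construction.
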