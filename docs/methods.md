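# Methods

`lassologit` implements two competing variable-selection models for a binary
mortality outcome in a clinical cohort, the protocol for comparing them, and
the synthetic-data machinery needed to exercise everything end to end.

## The two models

Both models are logistic regressions of a death indicator y ∈ {0, 1} on p
encoded covariates, η = β₀ + xᵀβ, Pr(y = 1) = eη / (1 + eη).

**Ordinary Lasso logistic regression** minimizes

    (1/n) Σᵢ [log(1 + e^{ηᵢ}) − yᵢ ηᵢ] + λ Σⱼ |βⱼ|

with an unpenalized intercept. The solver is penalized IRLS with cyclic
coordinate descent on the weighted least-squares surrogate (weights
wᵢ = pᵢ(1 − pᵢ), working response zᵢ = ηᵢ + (yᵢ − pᵢ)/wᵢ), soft-thresholding
each coordinate. Step-halving against the true penalized objective makes the
outer iteration monotone, so the objective never increases. At convergence
the subgradient (KKT) conditions hold: for active j,
(1/n) xⱼᵀ(y − p̂) = λ sign(βⱼ); for inactive j, |(1/n) xⱼᵀ(y − p̂)| ≤ λ.
λ is chosen on a 100-point log-spaced grid from
λ_max = maxⱼ |(1/n) xⱼᵀ(y − ȳ)| down to 10⁻⁴ λ_max by stratified 10-fold
cross-validation minimizing mean held-out binomial deviance (ties broken
toward the larger, sparser λ). The one-standard-error rule is available via
the stored deviance curve but λ_min is the default selection.

**Bayesian Lasso logistic regression** is the Park–Casella hierarchy carried
to the logistic likelihood:

    βⱼ | τ²ⱼ ~ N(0, τ²ⱼ)
    τ²ⱼ | λ² ~ Exponential(rate = λ²/2)
    λ² ~ Gamma(r = 10, δ = 10)
    β₀ ~ N(0, 100)

Marginally over τ²ⱼ the coefficient prior is Laplace with rate λ, the
Bayesian analogue of the L1 penalty; the Gamma hyperprior replaces
cross-validation. Sampling uses Pólya-Gamma augmentation, ωᵢ ~ PG(1, ηᵢ),
which makes every full conditional a named distribution:

* (β₀, β) | ω: Gaussian with precision ZᵀΩZ + diag(1/100, 1/τ²) and linear
  term Zᵀ(y − ½), Z = [1 X];
* 1/τ²ⱼ: Inverse-Gaussian(mean = √(λ²/βⱼ²), shape = λ²);
* λ²: Gamma(r + p, δ + Σⱼ τ²ⱼ/2).

The PG(1, z) draws come from the exact alternating-series accept/reject
sampler (Devroye type), implemented in-package and numba-compiled; its
correctness is pinned by the closed-form mean tanh(z/2)/(2z) and by an
independent Metropolis sampler targeting the un-augmented posterior.

Selection follows the credible-interval rule: a coefficient whose
equal-tailed 95% interval contains zero is reported as exactly zero,
otherwise as its posterior median. Equal-tailed (not HPD) intervals are a
deliberate choice: they are quantile-exact, invariant to monotone
transformation of the display scale (the OR scale), and the standard
reporting convention in clinical work.

## Comparison protocol

The cohort is split 60/40 into train and test; both models are fitted on
train (the Lasso with a fresh 10-fold CV inside the train part) and scored
on test with EBIC, AIC, sensitivity, specificity, accuracy and precision,
plus the per-variable selection indicator. The split/fit/score cycle is
repeated 100 times with per-repeat seeds spawned from one master seed; both
models share each split so the comparison is paired. Indices are averaged
over repeats (NaN values from zero-denominator ratios excluded with a
reported count) and variables are ranked by selection frequency, ties broken
by mean absolute coefficient.

Scoring conventions, all configurable:

* classification threshold 0.5; positive class = died;
* AIC = −2ℓ + 2(k + 1) and EBIC = −2ℓ + (k + 1) log n + 2γ log C(p, k) with
  γ = 0.5, the intercept always counted, n and ℓ from the test part;
* for the Bayesian model, k = number of CI-selected coefficients and ℓ is
  evaluated at the sparsified zero-or-median vector, so both models are
  scored on sparse point estimates of the same form.

## Simulation study

Covariates are zero-mean multivariate normal with corr(xᵢ, xⱼ) = ρ^|i−j|;
the outcome is Bernoulli(expit(xᵀβ)) with intercept 0. Scenario 1: p = 8,
β = (3, 1.5, 0, 0, 2, 0, 0, 0). Scenario 2: p = 9,
β = (2, −1, 0, 0, 1, −2, 0, 0, 0), with the first four covariates
dichotomized at the latent median (the latent draw preserves the
correlation; the stated coefficients multiply the observed 0/1 columns).
The grid crosses n_train ∈ {50, 100, 150} with ρ ∈ {0.2, 0.8}; the test set
has n_train/2 rows; each cell is replicated (default 50) with fresh data
per replicate, every cell/replicate independently seeded. Which covariates
are binary in scenario 2 is a convention (the first four) and configurable,
as is the dichotomization threshold.

## Synthetic cohort generator

The hospital registry behind the motivating analysis was never deposited,
so two synthetic stand-ins are provided.

* `simulate_cohort` draws 339 (configurable) patients with independent
  covariates at the published marginal frequencies (63.7% male, 77.6%
  adenocarcinoma, ...), age ~ N(62.84, 14.53²) truncated to (18, 100) years,
  and diagnosis-to-event duration ~ Gamma(shape 1.5, scale 12) months
  (median ≈ 14 months — a right-skewed, realistic follow-up distribution;
  the source table gives no distribution for it). Death follows a logistic
  model whose default effects are the reported log-odds: female +0.97,
  adenocarcinoma −1.96, −1.55 per SD of duration. The intercept is
  calibrated by bisection so the expected death proportion equals 0.575,
  using a 200,000-draw fixed-seed covariate sample, making the calibrated
  value deterministic and accurate to ~10⁻³. Covariates the published table
  omits (opium use, surgery, chemo- and radiotherapy, metastasis, family
  history) get field-plausible marginals documented in the source.
* `exact_margin_cohort` reproduces the published death-stratified level
  counts exactly by construction, filling each column independently within
  the alive/died strata. It exists so descriptive summaries are exactly
  checkable; its cross-covariate joint structure is synthetic and it should
  not be used to fit models of covariate interplay.

What passing tests on these data do and do not show: they verify the
estimators, the samplers and the protocol under a known generating process
with independent covariates (cohort) or AR(1) correlation (scenarios). They
do not certify the published real-data coefficient values, which depend on
the unavailable registry's joint covariate structure, missingness and
follow-up process.

## Numerical choices and defaults

* Coordinate-descent tolerance 1e−7 on the maximum coefficient change,
  10,000-sweep cap; weights floored at 1e−9. Path fits inside CV use the
  conventional 1e−5 weight floor and a bounded per-point iteration budget,
  then the selected λ is refit at full precision; the deviance curve's
  near-separable tail needs far less accuracy than the final fit.
* Continuous covariates are standardized at encoding; the penalized fitters
  additionally standardize all columns internally (penalty and prior
  fairness) and report coefficients back on the input scale.
* Gibbs defaults: 12,000 sweeps, 2,000 burn-in, no thinning; β = 0,
  τ²ⱼ = 1, λ² = r/δ at start; split-chain PSRF on β reported (not enforced).
  The repeated-split and simulation protocols use 3,000/500 chains: at
  n ≈ 200, p = 18 the sampler mixes with PSRF < 1.05 well before that, and
  the protocol needs hundreds of chains.
* τ² update guard: βⱼ² is floored at 1e−12 because the Inverse-Gaussian
  conditional mean is undefined at βⱼ = 0.
* Degenerate inputs: constant outcome → λ_max undefined (error); constant
  design column → retained but flagged; all-0/all-1 simulated outcome →
  one resample, then error; single-class CV fold → one reshuffle with a
  derived seed, then error; failed repeats are skipped and counted, never
  silently resampled.
* Every stochastic stage takes an explicit integer seed or spawns
  per-repeat seeds counter-style from one master seed; identical seeds give
  bitwise-identical results.

## Known limitations

* The cohort generator draws covariates independently; real registries have
  correlated risk factors (stage with metastasis, age with smoking), so
  selection-frequency results on synthetic cohorts are easier than life.
* No censoring-aware survival modelling: death status is treated as a fixed
  binary label, as in the motivating analysis.
* No missing-data machinery beyond complete-case filtering with a logged
  count.
* EBIC/AIC for the Bayesian model are computed at the sparsified
  zero-or-median vector; computing them at the full posterior median (or a
  posterior-predictive score) is an equally defensible convention and would
  shift the absolute index values, though not the protocol.
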