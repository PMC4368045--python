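# Methods

## Model and variance partition

The data model is the familiar single-factor random-slopes LMM

    y_ij = (β₀ + α₀ⱼ) + (β₁ + α₁ⱼ) x_ij + ε_ij,
    (α₀ⱼ, α₁ⱼ) ~ MVN(0, Σ),   ε_ij ~ N(0, σ²_ε),

with j indexing groups (individuals, sites, …) and Σ holding the random
intercept variance σ²_α0, the random slope variance σ²_α1 and their
covariance σ_α0α1.  More generally a random-effect term is a pair (Z, Σ)
with Z the n × k design over the covariates — first column all ones when
the term has an intercept — and Σ the k × k effect covariance.

The variance a term contributes at observation i is the quadratic form
zᵢ′Σzᵢ, the i-th diagonal entry of ZΣZ′.  Because the per-observation
random-effect distributions all have mean zero, their mixture over the
sample has variance equal to the mean of the individual variances,

    σ̄² = Tr(ZΣZ′)/n,

which is the term-level variance component entering marginal and
conditional R² and the ICC.  Three facts the test suite asserts directly:
it equals the intercept variance exactly when Z is a column of ones; at
x = 0 and x = 1 the observation variance is σ²_α0 and
σ²_α0 + 2σ_α0α1 + σ²_α1; and replacing x by c·x scales a slope-only term's
σ̄² by c².

The total variance is σ²_f + Σ_l σ̄²_l + σ²_e + σ²_d, with

- σ²_f: variance of the fixed linear predictor Xβ̂.  The sample variance
  (denominator n − 1) is used; the choice is not canonical, the difference
  from the population variance is O(1/n), and it matches the convention of
  the reference R implementation of these statistics.
- σ²_e: additive dispersion — the residual variance for Gaussian models;
  for other families it must be supplied (e.g. the variance of an
  observation-level random intercept).
- σ²_d: distribution-specific variance on the link scale: 0 (Gaussian,
  identity), π²/3 (binomial, logit), 1 (binomial, probit), 0.25 (Poisson,
  square root), ln(1 + 1/exp(β₀)) (Poisson, log).  Families beyond these
  five are rejected rather than approximated.  β₀ is taken as the mean of
  the linear predictor, which equals the fitted intercept exactly when the
  covariates are centred; the alternative — refitting after centring — is
  deliberately not implemented since the mean-predictor shortcut is exact
  for that purpose and cheaper.

Multiple random-effect terms are treated as mutually independent and their
σ̄² add.  Whether distinct terms may be correlated is genuinely open; the
independence assumption is flagged here rather than silently extended.

Conditioned ICC: at covariate value v the between-group variance is
[1, v]′Σ[1, v] (or [v]′Σ[v] for no-intercept terms; constant for
intercept-only terms), and ICC(v) = σ²_α(v) / (σ²_α(v) + σ²_e + σ²_d).

## Numerical choices

- σ̄² is computed as Tr(Σ·(Z′Z/n)) — never via the n × n product.  The
  equivalence is exact (cyclic trace) and tested to 1e−12 relative error
  against the dense form; dividing Z′Z by n *before* the trace keeps the
  random-intercepts reduction exact in floating point.
- Covariance validation symmetrizes within a relative tolerance of 1e−8
  and requires eigenvalues ≥ −1e−8 × spectral norm.  Diagonal entries of
  ZΣZ′ in (−1e−10, 0) — floating-point noise from boundary-PSD Σ — are
  clipped to zero; anything more negative raises.
- Rows with missing values in any used column are dropped (with a logged
  count) before any matrix is built.

## The REML/ML fitter

The Gaussian fitter exists so the whole pipeline runs without an external
mixed-model package.  Σ is parameterized through its relative Cholesky-like
factor, Σ = σ²_ε ΛΛ′ with Λ lower triangular (k(k+1)/2 parameters, diagonal
constrained ≥ 0), so estimates are PSD by construction and boundary fits
(zero variances) are representable.  β and σ²_ε profile out in closed form;
the criterion is evaluated per group via the Woodbury identity, factorizing
only the k × k matrix I + Λ′Zⱼ′ZⱼΛ, so cost is linear in n.  The profiled
−2 log-likelihood is

    ML:   n log(2πσ̂²) + log|V₀| + n
    REML: (n−p) log(2πσ̂²) + log|V₀| + log|X′V₀⁻¹X| + (n−p)

with V₀ = I + ZGZ′ the relative covariance and σ̂² the profiled residual
variance (denominator n for ML, n − p for REML).  The blocked evaluation is
tested against an explicit dense multivariate-normal oracle to 1e−8 (it
agrees to ~1e−14), and full fits are cross-checked against statsmodels
MixedLM.  Optimization uses L-BFGS-B from Λ₀ = 0.5·I, relative-criterion
tolerance 1e−8, at most 500 iterations.  REML is the default because the
variance components are the quantities of interest; ML is available for
nested-model comparisons.  Boundary fits are flagged (`boundary=True`) but
returned as valid partition inputs.  Non-Gaussian fitting is out of scope:
GLMM components are supplied externally through `ModelComponents` (the CLI
accepts them via a `components:` block).

## Synthetic data

`simulate_dataset` draws per-group effects from MVN(0, Σ) using an
eigendecomposition square root (valid for singular Σ, including Σ = 0),
covariates x ~ Uniform(0, 1) shared across groups by default, and Gaussian
noise or Poisson counts.  Group-specific covariate ranges induce the
unbalanced scenario.  One `numpy.random.default_rng(seed)` drives each
dataset; the spec serializes to JSON for provenance.

Default study conditions, chosen once as typical of a moderately powered
field study and used everywhere (tests, experiments, acceptance script):
100 groups × 10 observations, β = (0.5, 1), Σ = [[1, 0.25], [0.25, 0.5]],
σ²_ε = 1.  The canned *balanced* scenario uses 50 groups × 10 with the
shared U(0, 1) covariate; the *unbalanced* scenario gives one of 10 groups
80% of 500 observations and its own covariate range U(1, 2) against U(0, 1)
elsewhere, the situation where a random-intercepts fit biases the global
slope toward the dominant group.

What the generator does not emulate: non-normal random effects,
heteroscedastic or autocorrelated residuals, crossed or nested grouping
factors, covariate measurement error.  Passing recovery tests therefore
show the estimators are correct under the stated model, not that the model
fits any particular real dataset.

## Known limitations

- One grouping factor per term; binomial support restricted to binary
  responses; no confidence intervals on R² (no accepted method to wrap).
- The 2×2 variance components of a random-slopes model are weakly
  identified at 10 observations per group with x ∈ [0, 1]: their REML
  sampling SDs at the default conditions are ≈ 0.22 (intercept variance)
  and ≈ 0.23 (slope variance), as both this package's replicate runs and
  statsmodels' asymptotic standard errors show.  R² estimates are far more
  stable (mean absolute error < 0.05 at those conditions) because errors in
  individual components partly cancel in the ratios.
- Reports are validated with pydantic models; the JSON Schema file shipped
  under `schemas/` is generated from those models.
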