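# Methods

## The estimation problem

Bayesian comparison of two models rests on the model evidence
p(D | M) = ∫ p(D | M, θ) p(θ | M) dθ, and its ratio between models, the
Bayes factor.  For multilevel (mixed) Gaussian linear models the integral
runs over regression coefficients β ∈ R^d, group-level deviations
η_1..η_J ∈ R^m and variance parameters, and is analytically intractable
as a whole.  Monte Carlo estimators of the evidence degrade quickly with
the dimension of the sampled space, and d + Jm can easily dominate the
parameter count.

The approach implemented here marginalises every parameter with a
conditionally Gaussian role — β under its N(μ, Σ) prior and the η_j under
N(0, Σ_η) — in closed form, leaving an *integrated likelihood* that is a
function of variance parameters only (one to four dimensions for the
models shipped here).  A tempered sequential Monte Carlo (SMC) sampler
then estimates the remaining low-dimensional integral.  A *full* sampling
mode over (β, η, variances) is retained with the identical SMC engine so
the variance reduction bought by the marginalisation can be measured
rather than asserted.

## Model family

Four model kinds are supported, all with Gaussian observation noise:

| kind | mean structure | sampled parameters (integrated mode) |
|---|---|---|
| `linear` | β'x_i | σ² |
| `linear_nig` | β'x_i, β\|σ² ~ N(μ, γσ²Σ) | σ² (evidence also closed-form) |
| `multilevel_intercept` | β'x_ij + η_j | σ_y², σ_η² |
| `multilevel_general` | β'x_ij + η_j'z_ij | σ_y², ν |

For the general model the group covariance Σ_η is parameterised through a
vector ν.  Implemented structures: `diagonal`; `pair_correlation`
(ν = (σ₁², σ₂², ρ), off-diagonal ρσ₁σ₂); `banded_shared_rho` (adjacent
pairs share one correlation ρ, which may be fixed or sampled); and
`full_cholesky` (unrestricted, log-diagonal Cholesky vector).  Parameter
vectors outside the valid region (|ρ| > 1, non-positive variances,
non-positive-definite result) are treated as zero-probability points —
they return −∞ log likelihood rather than raising, so Metropolis
proposals can wander and be rejected.

## Closed-form marginalisation

All integrated likelihoods are pure functions of sufficient statistics
computed once from the data: Σxx', Σxy, Σy², and the per-group sums
Σ_i x, Σ_i y, Σ_i zz', Σ_i zy, Σ_i xz'.  For the linear model the
coefficient posterior at fixed σ² is N(μ̃, Σ̃) with
Σ̃⁻¹ = Σ⁻¹ + Σxx'/σ², and the log integrated likelihood is

    −½ ( log|Σ̃⁻¹| + log|Σ| + n log 2πσ² + μ'Σ⁻¹μ + Σy²/σ² − μ̃'Σ̃⁻¹μ̃ ).

The intercept-multilevel form integrates each η_j by completing the
square, producing per-group shrinkage factors
r_j = σ_η² / (σ_y² + n_j σ_η²) that correct the precision, the linear
term and the data quadratic, plus a Σ_j log((σ_y² + n_j σ_η²)/σ_y²)
volume term.  The general form replaces the scalars by per-group m × m
posterior precisions Σ̂η,j⁻¹ = Σ_η⁻¹ + Σ_i zz'/σ_y², each refactorised at
every variance point (they depend on it; only the data cross-products are
cached).  Under the conjugate normal-inverse-gamma prior
NIG(a, b, μ, γΣ) the σ² integral is also analytic, giving a closed-form
evidence used as the calibration anchor for the SMC estimator.

Numerical policy: every log-determinant and quadratic form goes through a
Cholesky factorisation of a precision matrix; no d × d matrix is
explicitly inverted (d reaches 145 in the radon no-pooling model).  If a
precision fails to factorise, a single jitter of 1e−10 × trace/d is added
and the event is logged; invalid variance points return −∞.  Empty
datasets short-circuit to an integrated likelihood (and NIG evidence) of
exactly 0, the log of an empty product of densities.

The single-level evaluator used inside SMC additionally exploits a one-off
generalised eigendecomposition of (Σxx', Σ): with L = chol(Σ) and
L'Σxx'L = Q diag(λ) Q', each σ² evaluation costs O(d) instead of O(d³),
which is what keeps the d = 87 and d = 145 radon models affordable at
thousands of particles.  Under the NIG prior the σ²-dependence collapses
further and each evaluation is O(1).

## Sequential Monte Carlo

The evidence estimator is static tempered SMC from prior (exponent
φ = 0) to posterior (φ = 1):

- **Adaptive tempering.** The next exponent is found by bisection so the
  relative effective sample size of the incremental weights
  exp(Δφ · loglik) matches `ess_threshold` (default 0.5); the final step
  is clamped so φ reaches exactly 1.
- **Resampling.** Systematic resampling every stage; the per-stage
  evidence increment log mean_i exp(Δφ ℓ_i) is accumulated in
  log-sum-exp form.  A constant likelihood therefore yields exactly zero
  log evidence in a single stage.
- **Mutation.** `mh_steps` (default 5) random-walk Metropolis sweeps per
  stage targeting prior × likelihood^φ, with proposal covariance
  2.38²/dim times the current particle covariance (floored).  Variance
  components are sampled as log σ² (the prior density carries the
  Jacobian); correlations on their natural scale with out-of-range
  proposals rejected through the prior.
- **Replication.** `n_runs` (default 8) independent runs from streams
  spawned off one master seed give a mean and an across-run standard
  deviation; the same seed reproduces the estimate bit for bit.

Full mode samples (β, η, variances) jointly: the hierarchical prior
(variances first, then β — conditionally on σ² for the NIG model — then
η | variances) is the initial distribution, and only the Gaussian
residual density of the data is tempered.

Defaults (2000 particles, 8 runs, threshold 0.5, 5 MH sweeps) match the
sampling effort used for the reference evidence tables this package
reproduces; the kernel settings themselves — adaptive bisected tempering,
systematic resampling, scaled random-walk mutation — are the field's
standard static-SMC recipe.

## Posterior summaries and recovery diagnostics

After integrated-mode sampling the coefficient posterior is the mixture
of the conditional Gaussians N(μ̃(v), Σ̃(v)) over the variance trace.
`pooled_beta_posterior` averages μ̃ and Σ̃ over the trace; because the
plain average of Σ̃ omits the spread of the conditional means, both that
variant (`within`) and the law-of-total-variance variant (`total`) are
computed and the choice is recorded in the output.

Recovery of a known coefficient vector b is scored two ways, matching the
two sampling modes: the integrated-trace distance
(1/N) Σ_n (b − μ̃_n)' Σ̃_n⁻¹ (b − μ̃_n) — an average of per-draw quadratic
forms, *not* a distance under a pooled covariance — and the full-trace
distance (b − β̄)' V⁻¹ (b − β̄) with the 1/(N−1) sample covariance of
explicit β draws.

## Synthetic data: what it emulates and what it does not

The generators emulate a seasonal-trend regression (Prophet-style): the
covariate vector g(t) stacks an intercept, hinge terms (t − s_k)1{t>s_k}
at changepoints s = (0, 0.2, 0.4, 0.6, 0.8), and a Fourier block, ordered
(intercept, trend, all cosines, all sines) to match a coefficient layout
(level, gradient changes, cosine amplitudes, sine amplitudes).  At the
default d₂ = 20 harmonics, d = 46.  Group membership is categorical with
Dirichlet(2, …, J+1) weights, giving deliberately unequal group sizes.
'True' coefficients are drawn from N(0, S) with S = blockdiag(S₁, λI),
λ = 0.001: the dense 6 × 6 block S₁ allows flexible interval gradients
while the small λ keeps the seasonal component subordinate.  Model priors
use the diagonal of S only (Σ = blockdiag(diag S₁, λI)) — deliberately
misspecified relative to the generator, so evidence comparisons reflect
structure, not prior sharpness.

Four dataset kinds correspond to the four model kinds (D0-D3).  Noise and
group variances are drawn from inverse-gamma distributions whose means
make E[var(y − b'x)] = 0.2 for every kind, so no dataset is intrinsically
easier.  Covariates and group structure come from a dedicated covariate
seed and are shared across kinds; coefficient/noise draws use independent
per-kind streams — the sharing is a testable contract.

What the generators do *not* emulate: heteroscedastic noise,
non-Gaussian residuals, missingness, covariate measurement error, or more
than two levels of nesting.  Passing tests on these data demonstrate
correctness of the marginalisation and calibration of the estimator, not
robustness to real-data pathologies.

A caveat learned from the study harness: the linear model with Gaussian
prior (M0) and with NIG prior (M3, γ = 1/E[σ²]) are near-twins — M3's
marginal coefficient prior is a heavy-tailed (multivariate-t) version of
M0's.  On data generated from either one, their evidences differ by
fractions of a nat with a data-draw-dependent sign, so "which twin wins"
is close to a coin flip at moderate n; discrimination between genuinely
different structures (single-level vs multilevel, intercept-only vs
correlated slopes) is robust.  This is a property of the models, not of
the estimator: the same pattern shows in the closed-form evidences.

## Radon case study

The loader standardises log radon (mean 0, sd 1 across measurements) and
log uranium (standardised across the county values, since it is a
county-level covariate); both transforms are recorded in the returned
metadata.  The floor indicator enters as the pair (1 − t, t) so basement
and first-floor measurements carry equal prior uncertainty.  Models
M0-M5 span complete pooling to varying slopes-and-intercepts; coefficient
priors are N(0, I) and every univariate variance has an IG(3, 1) prior;
M5's correlation has a truncated-normal prior on [−1, 1].

AIC uses the reference tables' parameter-count convention: for
single-level models
k is the number of identifiable coefficients (the rank of X — the
unpooled-intercept model M2 carries a redundant global intercept in its
Bayesian design, regularised by the prior, but it does not count towards
k); for multilevel models k adds the variance-covariance parameters.  The
maximised likelihood for multilevel models marginalises η into blockwise
covariances σ_y²I + Z_j Σ_η Z_j', profiles β by generalised least
squares, and optimises the variance parameters on the log scale (ρ via
atanh) with Nelder-Mead from three starts; a dense-covariance
optimisation oracle in the test suite confirms the profiled fit.

## Problem sizes used by the shipped checks

The self-contained checks run at sizes chosen to make every distribution
of interest measurable with tight Monte Carlo error while the whole suite
stays lightweight: oracle comparisons use n ≤ 10 with quadrature (d ≤ 2)
or 10⁶-draw Monte Carlo; SMC calibration uses an n = 200, d = 5 NIG model
where the evidence is analytic; the model-recovery study runs at n = 300,
J = 8, d₂ = 5 (d = 16) with 500 particles and 4 runs over 8 independent
replications; generator moments use 200 replications at the full n = 1000
scale.  The full-scale reference tables additionally require the
reference data files (see README): the exact realisations of the
published simulated datasets depend on seeds that are not derivable from
their description, so they must be supplied, not regenerated.

## Known limitations

- Gaussian likelihoods only; no GLM extension.
- Two-level nesting only.
- The SMC across-run standard deviations depend on kernel settings
  (tempering schedule, mutation counts); they are comparable in magnitude
  to, but not expected to match digit for digit, the spreads reported
  alongside the reference tables.
- Evidence values are prior-sensitive by design; the package deliberately
  provides no empirical-Bayes hyperparameter optimisation.
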