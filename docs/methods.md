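# Methods

## Model

`nmala` fits contrast-based network meta-analysis GLMMs with an arm-based
likelihood. Let trial *i* have arms *t₁ < t₂ < …* (the baseline *t₁* is the
trial's lowest-numbered treatment) and let *D(i)* be its design — the set of
treatments it includes. On the link scale,

    η(baseline arm)      = μ_i
    η(non-baseline arm)  = μ_i + d_{t₁t_k} + γ_{i,t₁t_k} + ω^{D(i)}_{t₁t_k}
                           + (x_i − x̄)·β

with likelihoods binomial–logit, normal–identity or Poisson–log. For the
normal family each arm contributes its sample mean with a *known* standard
error sd/√n; the arm-level sampling variance is not estimated. No continuity
corrections are applied anywhere — zero-event arms are handled by the exact
binomial likelihood.

Relative effects are spanned by basic parameters d_{1t} against a reference
treatment (configurable, default 1); every other contrast is the linear
combination d_{t₁t_k} = d_{1t_k} − d_{1t₁}. Because inference is joint and
Gaussian at each hyperparameter point, summaries of functional contrasts
computed through `FitResult.contrast` are exactly consistent with the
basic-parameter summaries.

Random-effect structure (per group, compound symmetric — "CS"):

* heterogeneity: γ_i ~ N(0, Σ_γ) per trial, Σ_γ with diagonal τ² and
  off-diagonal τ²/2 across the trial's contrasts;
* inconsistency (Jackson kinds): ω^D ~ N(0, Σ_ω) per **design**, diagonal κ²
  and off-diagonal κ²/2, the same vector entering every trial of the design.
  κ = 0 collapses the model onto the consistency model, which the engine
  exploits when `fixed_kappa=0` is requested (the ω slots are dropped).

The CS structure has closed-form inverse and determinant
(Σ⁻¹ = 2/v (I − J/(m+1)), log|Σ| = m log(v/2) + log(m+1)), used directly in
the prior precision. For the samplers and the simulator the equivalent
shared + idiosyncratic decomposition is available (`cs_decompose`): for m ≥ 2
effects, e_k = a + b_k with Var(a) = Var(b_k) = v/2 reproduces the CS
covariance exactly; a single effect uses one component at variance v.

Meta-regression uses one constant interaction coefficient β for all
treatments versus the reference (the richer exchangeable/unrelated
interaction variants are deliberately out of scope). Covariates are centered
at the mean over the retained trials; trials missing the covariate are
dropped (and logged) before fitting. β cancels from contrasts between two
non-reference treatments, which the tests assert both algebraically and
numerically.

Priors: independent N(0, `prior_fixed_sd`² = 1000) on μ, d, β; uniform on
[0, 5] for τ and κ on the standard-deviation scale (both bounds
configurable, e.g. U[0, 2] for sparse networks where the likelihood carries
little information about the tails).

## Nested Laplace inference

The model is a three-stage latent Gaussian model with latent field
α = (μ, d, β, γ, ω) and hyperparameters Ψ = (τ², κ²). The engine works on
θ = log(sd²) internally; the uniform-on-sd prior is transformed with its
exact Jacobian. This keeps the hyper optimization unconstrained and the
curvature well scaled.

1. **Gaussian approximation.** For fixed θ, Newton iterations (analytic
   gradient and Fisher information, step-halving line search) maximize
   log p(α | θ, y) to gradient norm 1e-8 (max 100 iterations; failure raises
   with the gradient trace). The curvature at the mode is kept as a Cholesky
   factor.
2. **Hyperparameter posterior.** The Laplace formula
   p̃(θ|y) ∝ p(y|α*) p(α*|θ) p(θ) / p̃_G(α*|θ, y) is evaluated at the
   conditional mode α*(θ). Its mode is located by Nelder-Mead (tolerance 1e-6
   on the log density; derivative-free because the prior support has hard
   edges), and the Hessian is formed by central differences with step 0.02 on
   the θ scale — large enough that the O(100) log-density values do not lose
   the second difference to rounding. Exactness in the Gaussian limit: for
   normal endpoints p̃(θ|y) *equals* the marginal likelihood of the linear
   mixed model; the tests verify this to 1e-6 and also check the binomial
   mode against an independent numerical optimizer.
3. **Integration.** Default is a dense axis-aligned grid in coordinates
   standardized by the marginal standard deviations at the mode: step 0.5,
   each axis extended until the log density drops 6 below the mode (capped
   at 25 steps with a warning — reached only for nearly flat posteriors,
   e.g. κ on strongly consistent data). A central composite design
   (`strategy="ccd"`) is available: center plus satellites on the sphere of
   radius 1.65·√q in fully standardized coordinates, with weights chosen so
   a Gaussian density would be integrated with exact mean and covariance
   (9 points for q = 2). The grid is the reference; CCD is the cheap
   approximation and is validated against the grid in the tests.
4. **Marginals.** Each latent marginal is the weight-mixed Gaussian
   conditional N(m_i(θ_j), s_i²(θ_j)) tabulated on ±6 mixture standard
   deviations (401 points). The conditional means carry a third-order
   skewness correction, E[α] ≈ α* + ½ Σ Xᵀ(ℓ'''(η*) ⊙ var(η)) — the
   first-order content of the simplified Laplace approximation. Without it,
   binomial posterior medians sit visibly below the MCMC oracle
   (≈ 2–3 Monte-Carlo standard errors on desk-scale networks) and DIC is
   biased upward by ≈ 1.5; with it the engine matches the sampler within
   Monte-Carlo error. The correction vanishes identically for normal
   endpoints. A full per-slot nested Laplace profile (re-optimizing the
   remaining latents over a grid of slot values) is available behind
   `laplace_marginals=True` / `--laplace-marginals` for the reported d and β
   marginals.
   Hyperparameter marginals collapse the dense grid over the other axis,
   interpolate the log profile with a cubic spline on the θ scale and
   transform to the sd scale with the exact Jacobian; equi-tailed intervals
   come from inverse-CDF interpolation on the density grid.
5. **DIC.** Deviance is −2 log p(y|α) including all normalizing constants
   (a `saturated` convention is available as an option; pD is invariant to
   the choice). The posterior mean deviance is computed *deterministically*:
   under each integration point the linear predictor of an arm is Gaussian,
   so E[D] is a per-arm 20-point Gauss-Hermite quadrature, mixed over the
   grid; pD = D̄ − D(ᾱ) at the posterior mean of the latent field. This
   avoids Monte-Carlo noise of the same order as the agreement one wants to
   demonstrate. Fixed-effect fits skip hyper integration entirely (a single
   Gaussian approximation), and their pD reproduces the free parameter count
   to within a few percent.

Determinism: the Laplace engine uses no random numbers, so repeated fits are
bit-identical; the `seed` option is recorded in the run manifest and feeds
only the MCMC engine.

## MCMC oracle

`sample_posterior` is a random-walk Metropolis-within-Gibbs sampler over the
same posterior, used as the validation oracle and as an alternative backend.
Random effects are sampled in the shared + idiosyncratic decomposition, which
makes the scalar blocks conditionally independent; blocks whose components
touch disjoint arms (all μ, all idiosyncratic components, per-design shared
components, ...) are updated in parallel, vectorized across chains. Basic
parameters d overlap in arms and are updated one at a time. τ and κ are
updated on the log-sd scale with the uniform-prior Jacobian. Proposal scales
adapt toward 30–40% acceptance during burn-in only, preserving detailed
balance afterwards. Defaults mirror common long-run settings (30k burn-in,
50k sampling, thin 5, 3 chains); tests and examples scale down to a few
thousand sweeps, where the sampler still passes Gelman-Rubin < 1.05 on
desk-scale networks. Summaries report batch-means Monte Carlo standard
errors for both means and medians; the classic (non-split) Gelman-Rubin
statistic is computed per scalar parameter.

## Synthetic data

`simulate_network` draws from exactly the generative model above: μ_i ~
N(mu_mean, mu_sd²) (a dispersed nuisance; default sd 1), γ per trial from
CS(τ), ω once per design from CS(κ) — shared by all its trials, which is the
defining feature of design-level inconsistency and is asserted in tests —
and outcomes from the requested family. Defaults: binomial arms of n = 100
patients, which keeps desk-scale networks well identified. Fixtures
reproduce familiar topologies (`toy_s23`: 3 trials / 3 designs / 4
inconsistency slots; `smoking_like`: 24 trials, 4 treatments, two 3-arm
trials, 8 designs; `diabetes_like`: 26 continuous-endpoint trials, 10
treatments, 16 designs) with simulated outcomes.

What the simulator does *not* emulate: real networks' skewed arm sizes,
systematically varying baseline risks, non-normal random effects, outcome
reporting quirks (e.g. follow-up heterogeneity) and covariate confounding.
Passing recovery and coverage tests therefore demonstrates correctness of
the implementation under its own assumptions, not robustness to their
violation.

## Problem sizes and tolerances in the test suite

Unit and property tests run on 3–12-trial networks; the oracle-equivalence
check uses a 6-trial network with 3 chains × 26k sweeps (agreement within 3
batch-means MCSEs); interval coverage uses 50 seeded 8-trial replicates
(expecting ≥ 88% coverage of 95% intervals); the bundled 24-trial smoking
network exercises the full pipeline, where a Jackson fit takes about one
second. Normalization of every reported marginal is checked to 1e-6, the
Gaussian-limit identities to 1e-6, and the κ = 0 reduction of the Jackson
model to the consistency model to 0.01.

## Known limitations

* Loop-inconsistency (Lu-Ades) models, node splitting, arm-based pooling,
  t-distributed random effects, WAIC and treatment-ranking probabilities are
  out of scope.
* Marginals are univariate; joint latent draws (needed for ranking
  probabilities) are not produced by the nested-Laplace pipeline.
* The hyper posterior is explored on at most a 2-D grid (τ, κ); models with
  more hyperparameters would need the CCD path generalized.
* For binary networks with very sparse cells the Gaussian/skew-corrected
  conditionals inherit the known inaccuracy of Laplace-type approximations;
  the MCMC backend is the fallback there.
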