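# Methods

## Model

Let U, V > 0 be two biomarkers with gamma marginals in the rate/shape
parameterization, f(x; λ, δ) = λ^δ/Γ(δ) · x^{δ−1} e^{−λx} (mean δ/λ).  Their
joint CDF is built with the Frank copula,

    F_{U,V}(u, v) = C_θ(F_U(u), F_V(v)),
    C_θ(a, b) = −(1/θ) log[1 + (e^{−θa} − 1)(e^{−θb} − 1)/(e^{−θ} − 1)],

θ ≠ 0, with θ → 0 recovering independence.  The Frank family is radially
symmetric, covers the full dependence range, and θ maps one-to-one onto
Kendall's τ through τ(θ) = 1 + (4/θ)(D₁(θ) − 1) with D₁ the first
Debye-type integral.  The three association strengths used throughout the
benchmark presets, |θ| ∈ {1, 5, 10}, correspond to |τ| ≈ 0.11, 0.46, 0.67.

The target of inference is the ratio R = U/V.  Conditioning on V gives its
CDF as a single integral over the copula's conditional distribution,

    F_R(r) = ∫₀¹ ∂C_θ(a, b)/∂b |_{a = F_U(r F_V^{-1}(s)), b = s} ds,

and differentiating under the integral gives the density.  Substituting the
standardized gamma quantile q_s = P^{-1}(δ_V, s) (P the regularized lower
incomplete gamma function) shows that the law of R depends on the rates
only through Λ = λ_U/λ_V:

    f_R(r) = ∫₀¹ c_θ(P(δ_U, rΛq_s), s) · Λ^{δ_U} r^{δ_U−1} q_s^{δ_U}
             e^{−rΛq_s} / Γ(δ_U) ds.

At θ → 0 this is the GB2 density Λ^{δ_U} r^{δ_U−1}(1 + Λr)^{−(δ_U+δ_V)} /
B(δ_U, δ_V), which the code uses both as a fast special case and as an
independent oracle in the tests.

### Regression structure

Covariates enter via log λ_U|x = x′β_U, log λ_V|x = x′β_V and, optionally,
θ|x = x′β_θ (identity link; θ needs no positivity constraint).  The shapes
δ_U, δ_V are covariate-free and constrained to exceed 1 so that both
marginals are unimodal and right-skewed, the typical shape of biomarker
distributions.  Because log Λ|x = x′(β_U − β_V), the derived coefficients
β_Λ = β_U − β_V summarize covariate effects on the ratio scale.

The log-likelihood is the sum over observations of
log c_θ(F_U(u_i), F_V(v_i)) + log f_U(u_i) + log f_V(v_i) with row-specific
parameters.  Note that fitting maximizes this *joint* likelihood of
(u, v) — not the ratio likelihood — which is what lets the model pool
information across both components.

## Estimation and inference

* **Optimization.** L-BFGS-B on an unconstrained scale; the shape
  constraint is handled by the smooth reparameterization δ = 1 + exp(ψ),
  keeping quasi-Newton updates and the Hessian well defined.  Non-converged
  runs are retried from up to 3 seeded jitters of the start.
* **Initialization** is deterministic: independent log-link gamma GLMs of u
  and v give the rate coefficients (log λ = log δ − log μ), moment matching
  of the standardized residuals gives the shapes (clamped to [1.2, 100]),
  and the empirical Kendall τ of (u, v) is pushed through the τ→θ inverse
  (clamped away from 0) for the association intercept.
* **Posterior approximation.** With flat priors, γ | data ≈
  N(γ̂, J⁻¹(γ̂)) where J is the observed information of the negative
  log-likelihood, computed by central finite differences with per-coordinate
  steps h_j = max(10⁻⁴, 10⁻⁴|γ̂_j|) on the optimization scale.  Draws
  (default 10,000) are taken on that scale and shape columns mapped back
  through δ = 1 + exp(ψ); percentile intervals are equivariant under this
  transform, so intervals for δ respect δ > 1 by construction.  A
  non-positive-definite information matrix raises an error carrying the
  eigenvalues rather than being silently repaired.
* **Intervals** are type-7 empirical percentiles of the draws.  Intervals
  for derived quantities (β_Λ coefficients, user transforms) are percentiles
  of the transformed draws, never transforms of interval endpoints.
  One-dimensional significance statements are reported only as "the interval
  excludes zero"; no bespoke test statistic is invented.
* **Prediction.** For a profile x̃, plug Λ̂ = exp(x̃′(β̂_U − β̂_V)),
  θ̂ = x̃′β̂_θ, δ̂_U, δ̂_V into the ratio law; medians and quantiles come
  from inverting the CDF, the conditional mean from integrating r·f_R.

## Numerics

* **Quadrature.** Ratio density and CDF use Gauss–Legendre quadrature on
  s ∈ (0, 1): 256 nodes by default (node layouts are cached), 128 for bulk
  conditional-median work where ~10⁻⁵ accuracy suffices, 1024 in tests that
  cross-check the two analytic forms of the density to 10⁻⁶.  Nodes are
  interior, so the integrable endpoint growth of the gamma quantile needs no
  special treatment; the adaptive-quadrature cross-check clips s to
  [10⁻¹⁰, 1 − 10⁻¹⁰].  Density sums are log-sum-exp so tail evaluations do
  not underflow.
* **Copula stability.**  The copula log-density is evaluated through the
  identity D = e^{−θu} + e^{−θv} − e^{−θ} − e^{−θ(u+v)} with a max-scaled
  signed exponential sum, stable for |θ| up to ~300 of either sign; |θ| <
  10⁻⁶ routes to the exact independence forms everywhere (density 1, C = uv,
  GB2 ratio law), since the closed forms are 0/0-indeterminate near θ = 0.
  During optimization θ is clipped to ±300 and linear predictors to ±50, and
  a non-finite log-likelihood returns a finite −10¹² sentinel so line
  searches can recover.
* **Quantile inversion.** Scalar quantiles bracket around the GB2 quantile
  (exact at independence) by doubling/halving, then Brent refinement to
  10⁻⁸ relative tolerance.  Batched medians use vectorized bisection from
  the same seed — efficient because the median of R is nearly invariant in
  θ, so the independence median is already within a few percent.
* **Kendall τ.** The Debye-type integrand t/(e^t − 1) has its removable
  singularity at t = 0 patched explicitly; the inverse mapping is Brent
  root-finding on a doubling bracket.

## Synthetic-data generator

The generator defines the benchmark conditions.  Covariates are X₁, X₂ ~
N(0, 1) and X₃, X₄ ~ Bernoulli(0.5), pairwise equicorrelated through a
4-dimensional latent Gaussian with correlation 0.4, with the binaries
obtained by dichotomizing their latents at zero.  A threshold construction
cannot make all *realized* Pearson correlations 0.4 for mixed pairs: the
realized values are 0.4 (normal–normal), 2·0.4/√(2π) ≈ 0.319
(normal–binary) and 2·arcsin(0.4)/π ≈ 0.262 (binary–binary).  This
attenuation is documented by `realized_covariate_correlation` and verified
empirically in the tests; it is the simplest construction consistent with
the stated marginals and latent equicorrelation.

Outcome pairs are sampled by conditional inversion: (w, t) uniform, the
Frank conditional CDF inverted in closed form for the second uniform, then
both pushed through the gamma quantile functions.  Row-specific θ_i values
are supported; rows whose θ_i falls inside the independence guard are drawn
independently.

Preset scenarios: study 1 (negative association θ₀ ∈ {−1, −5, −10},
β_U = (0, 0.4, −0.4, 0.2, −0.2), β_V = (0, −0.2, 0.2, −0.4, 0.4), δ = (2, 6));
study 2 (positive association θ₀ ∈ {1, 5, 10}, β_V = (0, 0.2, −0.2, 0.4, −0.4),
δ = (2, 2)); study 3 (covariate-dependent association β_θ = (0, 1, −1, 0.5,
−0.5) with study-1 rates and shapes).  Test sets redraw covariates and
outcomes from the same configuration on a disjoint seed stream.

What the generator does *not* emulate: real biomarker panels have
measurement error, detection limits, batch effects and non-gamma marginal
shapes.  Passing the replicated experiments therefore demonstrates
correctness of the estimator under its own assumptions (internal validity),
not robustness to such violations.

## Experiments and scoring

Experiments are pure functions of (scenario, replications, seed); replicate
i derives its training stream from seed + i and its test/posterior streams
from disjoint seeded substreams, so summaries are bitwise reproducible.
Replicates with optimizer failures are dropped and counted (none occur
under the preset scenarios at the shipped replication levels).  Default
replication is 1000, the scale at which the reference results are
quoted; the shipped experiment scripts use 100–300 replicates per scenario
— enough for binomial 99% bands on coverage proportions and ~3-standard-
error resolution on mean RMSE — with exact binomial bands / replicate
standard errors computed at the replication actually used.

Cross-model predictive log-likelihood is evaluated on the **ratio scale**
for every model, including the copula model (whose density of R is the
quadrature integral at the fitted parameters): the univariate benchmarks
define no joint law for (U, V), so the ratio scale is the only common
footing.  A joint-scale evaluation is available via
`predictive_log_density(..., scale="joint")` for sensitivity analysis.

CRPS uses the standard sample estimator mean|Xᵢ − r| − ½·mean|Xᵢ − Xⱼ| with
the O(S log S) sorted-pairs identity, reported lower-is-better; a "skill"
orientation flag negates it, since both conventions appear in applied work.
The quantile decomposition reports QS_α = 2(1{r ≤ q_α} − α)(q_α − r) whose
integral over α recovers the CRPS (verified in tests to 1%).

## Design choices where the design was open

* **δ > 1 via smooth reparameterization** rather than box constraints:
  keeps the Laplace approximation on an unconstrained scale and makes
  percentile intervals respect the constraint automatically.
* **CDF form.** The CDF is implemented as the integral of the copula's
  conditional distribution ∂C/∂b — the directly integrable representation —
  and is validated against two independent oracles (finite differences of
  the density integral, and the empirical CDF of 10⁵ sampled pairs).
* **Production density formula.** The Λ-parameterized form is the
  production path (it exposes the identifiable parameter and needs one
  incomplete-gamma inversion per node); the two-marginal change-of-variables
  form is retained as a test oracle.
* **Benchmark LSS fits** (location–scale variants) are direct joint MLEs by
  quasi-Newton, not backfitting: simpler, and exact at the optimum.

## Limitations

* Only the Frank copula and gamma marginals are implemented; the model
  surface would admit other copulas/marginals but no hook is exercised.
* Linear predictors only; shapes are covariate-free.
* The normal posterior approximation can misrepresent strongly skewed
  likelihood surfaces at very small n; the coverage experiments validate it
  down to n = 200 under the preset scenarios only.
* Pooled (marginal) dependence in simulated data differs from the copula's
  conditional τ whenever covariates affect both components — a feature of
  the model, but worth remembering when eyeballing raw correlations.
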