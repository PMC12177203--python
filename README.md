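# fcgam — copula regression for ratios of correlated biomarkers

Many clinical endpoints are ratios of two positive, *dependent* biomarkers:
amyloid-β 42 / total-tau in dementia research, LDL/HDL cholesterol, CD4/CD8
lymphocyte counts.  Standard practice either log-transforms the ratio and
runs a Gaussian regression, or assumes the components are independent.
Neither respects the joint behaviour of the components — in particular the
*negative* association between amyloid-β and tau.

`fcgam` implements a distributional regression model for the ratio
R = U/V in which

* U and V carry gamma marginals in the rate/shape parameterization,
  f(x) = λ^δ/Γ(δ) · x^{δ−1} e^{−λx},
* their joint law is tied by a **Frank copula** C_θ, whose association
  parameter θ ∈ ℝ∖{0} covers the full range of negative and positive
  dependence and maps monotonically onto Kendall's τ via a Debye-type
  integral,
* the covariates enter through log λ_U = x′β_U, log λ_V = x′β_V and
  θ = x′β_θ (or a constant θ), with the shapes δ_U, δ_V > 1 as
  covariate-free nuisance parameters.

The ratio law depends on the rates only through Λ = λ_U/λ_V, so
log Λ|x = x′(β_U − β_V) gives directly interpretable covariate effects on
the ratio.  The ratio's density and CDF are one-dimensional integrals over
the copula (evaluated by Gauss–Legendre quadrature); at θ → 0 the law
reduces to the generalized beta distribution of the second kind (GB2).
Fitting is joint maximum likelihood (quasi-Newton with δ = 1 + exp(ψ)
handling the shape constraint); finite-sample inference uses percentile
credible intervals from the normal posterior approximation
γ | data ∼ N(γ̂, J⁻¹(γ̂)) under flat priors.

The package also ships the surrounding benchmark apparatus: a synthetic
data generator with preset simulation scenarios, the comparison families
(GB2, log-normal and gamma regressions plus their location–scale–shape
variants), replicated coverage / RMSE / predictive-log-likelihood
experiments, and CRPS scoring with its quantile decomposition.

## Worked example

```python
import numpy as np
from fcgam import (SimConfig, simulate_dataset, fit_mle, sample_posterior,
                   credible_intervals, predict_ratio_law, ratio_quantile)

# a negatively associated scenario: Kendall tau(theta=-5) ~ -0.46
data, truth = simulate_dataset(SimConfig.study1(theta0=-5.0, n=500, seed=1))

fit = fit_mle(data, data.default_spec("constant"), seed=1)
print(f"theta_hat = {fit.estimate.beta_theta[0]:.3f}, "
      f"tau_hat = {fit.kendall_tau_at_intercept:.3f}")
print(f"shapes   = ({fit.estimate.shape_u:.2f}, {fit.estimate.shape_v:.2f})")

draws = sample_posterior(fit, n_draws=10000, seed=2)
table = credible_intervals(draws, level=0.95)
print(table.loc[["beta_u[x1]", "beta_v[x1]", "beta_lambda[x1]"]].round(3))

law = predict_ratio_law(fit, np.zeros(4))     # reference covariate profile
print(f"predicted median ratio at x=0: {ratio_quantile(0.5, law):.3f}")
```

Output:

```
theta_hat = -4.680, tau_hat = -0.436
shapes   = (1.93, 6.02)
                  mean  median  lower  upper  excludes_zero
parameter
beta_u[x1]       0.335   0.336  0.267  0.401           True
beta_v[x1]      -0.191  -0.191 -0.229 -0.152           True
beta_lambda[x1]  0.526   0.526  0.433  0.618           True
predicted median ratio at x=0: 0.295
```

The generating values were β_U1 = 0.4, β_V1 = −0.2 and θ = −5 (τ = −0.46);
the 95% credible intervals for β_V1, θ and the shapes cover their targets,
and the derived rate-ratio coefficient β_Λ1 = β_U1 − β_V1 is reported with
an interval computed from the differenced posterior draws.  The predicted
median at the reference profile (0.295) sits on top of the true conditional
median (0.296 for Λ = 1, δ_U = 2, δ_V = 6, θ = −5).

A command-line interface mirrors the library:

```bash
fcgam simulate --study 1 --theta0 -5 --n 500 --seed 1 --out data.csv
fcgam fit --data data.csv --theta-mode constant --seed 2 --out fit.json
fcgam predict --fit-json fit.json --data data.csv --out pred.csv
fcgam evaluate --study 1 --theta0 -1 --n 500 --metric rmse --reps 50 --seed 3 --out rmse.json
```

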