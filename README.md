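# fieldspat

Spatial regression for field trials: simulation, estimation and
evaluation when observations on a field are **spatially autocorrelated**
(SAC). Built for agronomists, plant scientists and biostatisticians who
relate an outcome measured across a field (yield, biomass, a phenotype)
to continuous regressors (vegetation indices, genomic scores) or to an
experimental treatment, and who need hypothesis tests, coefficient
estimates, feature selection and honest predictive-performance estimates
that are not distorted by spatial structure.

## The models

Data live on an equispaced grid with integer coordinates. An outcome
`A` and regressors `B_1..B_p` are modeled (and simulated) as
multivariate normals whose mean surface or covariance carries one of
four spatial structures: none, a linear gradient `f(x,y) = (x,y)'γ`, an
edge effect `f(x,y) = β_edge · d_edge(x,y)`, or Gaussian-decay
autocorrelation

```
Σ = σ² (τ I + (1−τ) Σ_gauss),   Σ_gauss[i,k] = exp(−(d_ik / r)²)
```

with range `r`, nugget `τ` and variance `σ²`.

**GLS** (`SpatialGLS`) alternates restricted-maximum-likelihood
estimation of `(σ², r, τ)` from the residuals with least squares on
outcome and design premultiplied by the inverse square-root factor
`Σ̂^{−1/2}` (whitening), and reports Wald tests for the coefficients.

**GLS elastic net** (`SpatialElasticNet`, variant `"pengls"`) carries
the same idea into high dimensions (`p ≫ n`) by minimizing

```
(A − β₀ − Bβ)' Σ̂⁻¹ (A − β₀ − Bβ) + λ (α‖β‖₁ + (1−α)/2 ‖β‖₂²),  α = 0.5
```

alternating whitened elastic-net fits with REML covariance
re-estimation, starting from Σ = I, until the mean squared change in
predictions drops below 2.5e-4. This reduces **red-shift** — the
preferential selection of spatially structured features by spatially
naive selectors.

The evaluation layer provides spatially **blocked cross-validation**
(k-means folds), the mean-centered R², inverse-distance **Moran's I**
(marginal and conditional, with the null expectation −1/(n−1)
subtracted), and feature-selection metrics including the spatial share
of the selections.

## Worked example

```python
import numpy as np
from fieldspat import (ScenarioSpec, simulate_observational, SpatialGLS, fit_ols)

ds = simulate_observational(
    p=1, n=100, G=15,
    outcome_spec=ScenarioSpec.gauss_cor(),    # r=7.5, tau=0.25, sigma2=1
    regressor_spec=ScenarioSpec.gauss_cor(),
    spatial_fraction=1.0, seed=7, beta=0.5)

res = SpatialGLS(ds.A, ds.B, ds.design).fit()
print(res.summary())
```

prints

```
Spatial GLS regression results
  nobs: 100   df_resid: 98   loglik: -91.027
  covariance: sigma2=0.4741  r=5.266  tau=0.6084   (REML, 2 iter, converged)
                    coef          se         t     P>|t|
  intercept     -0.00820     0.20323    -0.040    0.9679
  B_1            0.60906     0.11487     5.302    0.0000
```

The fitted covariance detects spatial structure (the generating values
were `r=7.5`, `τ=0.25`; range and nugget estimates are individually
very variable, which is expected for this model). The coefficient
estimate 0.609 (true 0.5) is clearly significant, and its standard
error accounts for the spatial correlation — an OLS fit of the same
data (`fit_ols(ds.A, ds.B)`) reports a smaller standard error (0.090)
by wrongly assuming independent errors.

A high-dimensional fit with CV-tuned penalty:

```python
from fieldspat import SpatialElasticNet, random_folds
ds = simulate_observational(p=100, n=50, beta_sd=0.5,
                            outcome_spec=ScenarioSpec.linear(),
                            regressor_spec=ScenarioSpec.linear(), seed=3)
fit = SpatialElasticNet(ds.A, ds.B, ds.design, variant="pengls").fit(
    folds=random_folds(50, 5, seed=1))
print(fit.selected.size, "features selected at lambda", round(fit.lam, 4))
# -> 20 features selected at lambda 2.2841
```

## Command line

```sh
fieldspat simulate --scenario-outcome edge --scenario-regressor linear \
    --p 50 --n 100 --grid 15 --seed 1 --out data.csv
fieldspat fit --method pengls --cv blocked --folds 5 --data data.csv --out fit.json
fieldspat bench --study highdim --reps 50 --methods en,pengls --seed 7 --out results/
```

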