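# gwwr — geographically weighted Weibull regression

`gwwr` fits parametric Weibull regression models to **right-censored,
spatially heterogeneous, nonnegative continuous responses** — the
motivating case being dissolved oxygen (DO) in river monitoring networks,
where DO readings at or above a quality threshold (e.g. 6 ppm) are
recorded as censored and readings below it are "events" (water-quality
degradation). The package covers the global model, its locally weighted
(geographically weighted) extension, the full inference suite,
diagnostics, effect-ratio interpretation, and a seeded synthetic-data
generator so everything is testable without access to any monitoring
dataset.

## Model

The response follows a scale–shape Weibull with density

    f(y) = λ γ y^(γ−1) exp(−λ y^γ),   λ = τ^(−γ),

and covariates act on the rate-style scale,

    λ(x) = exp(bᵀx),   x = (1, X₁, …, X_p),

so the hazard h(y, x) = γ y^(γ−1) exp(bᵀx) is proportional-hazards in x,
and the mean is μ(x) = Γ(1 + 1/γ) exp(−bᵀx / γ). With right censoring at
y\* (event indicator δᵢ = 1{yᵢ < y\*}) the log-likelihood is

    ℓ(φ) = Σᵢ δᵢ[log γ + (γ−1) log yᵢ + bᵀxᵢ] − yᵢ^γ exp(bᵀxᵢ),

with φ = (γ, b) estimated by damped Newton–Raphson using the analytic
gradient and Hessian; var(φ̂) = −H(φ̂)⁻¹ (inverse observed information).

The **geographically weighted** model lets φ vary by site: φ(uᵢ) maximizes
the kernel-weighted log-likelihood Σⱼ wᵢⱼ ℓⱼ(φ) with adaptive Gaussian
(or bi-square) weights wᵢⱼ = exp(−½ (dᵢⱼ/aᵢ)²). The per-site bandwidth aᵢ
minimizes BIC(uᵢ) = −2 ℓ(φ̂(uᵢ)) + K log n over a log-spaced candidate
grid that includes the infinite (all-weights-one) candidate, under which
every local fit reduces exactly to the global fit.

Inference: Wilks likelihood-ratio and Wald tests for the global model;
a GWWR-vs-global similarity test, a simultaneous local-slope test
(each χ² with n·p df, likelihood or quadratic-form flavours), and
per-site Wald tests from which sites are grouped by their significant
covariate sets. Diagnostics: VIF, the Glejser heterogeneity screen, exact
finite-sample Kolmogorov–Smirnov distribution checks, BIC / GCV /
McFadden R² / MAPE, and Wald-driven backward elimination.

## Worked example

```python
from gwwr import WeibullRegression, GWWR, KernelConfig, backward_eliminate
from gwwr.simulate import river_study_fixture

sample = river_study_fixture(seed=0)     # 27 sites, 10 covariates, y* = 6
final, trace = backward_eliminate(sample, alpha_stay=0.10)
print(final.summary())
```

```
Censored Weibull regression (MLE)
  n = 27, events = 20, loglik = -31.1619, BIC = 75.5072
  converged: True in 8 iterations
       param     estimate    std err        z      P>|z|
       shape       7.7590     1.5409   5.0354  4.768e-07
   Intercept     -15.1892     2.9581  -5.1347  2.825e-07
          Fe       2.0698     0.8612   2.4034    0.01624
     nitrate       0.3642     0.1634   2.2287    0.02583
```

20 of 27 synthetic sites (74%) are below the 6-ppm threshold. Backward
elimination retains dissolved iron and nitrate; both Wald statistics
exceed 1.96. A positive coefficient raises λ(x), i.e. raises the
degradation hazard and lowers mean DO: the hazard ratio for +1 ppm iron is
exp(2.0698) ≈ 7.9 and the mean-DO ratio exp(−2.0698/7.759) ≈ 0.766. The
simultaneous Wilks test gives W = 12.0231 on 2 df (p = 2.45e-3): the
retained covariates jointly matter.

The local model and its comparison with the global one:

```python
gw = GWWR(final.sample, KernelConfig(kind="gaussian")).fit()
print(gw.summary())                 # per-site bandwidths and fits
print(gw.similarity_test())         # GWWR vs global, df = n*p
print(gw.site_measures().tail(1))   # regional averages of S, F, h, mu
```

A command-line interface mirrors this workflow
(`gwwr check`, `gwwr fit`, `gwwr simulate`); `gwwr fit` writes
`global_params.csv`, `local_params.csv`, `tests.csv`, `measures.csv`,
`ratios.csv` and `gof.json` with 6-significant-digit formatting so reruns
are byte-identical.

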