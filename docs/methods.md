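# Methods

## Model and assumptions

The response Yᵢ > 0 at site i follows a scale–shape Weibull,
f(y) = λγy^(γ−1)exp(−λy^γ), with the rate-style scale linked to
covariates through λ(x) = exp(bᵀx). This is a proportional-hazards
specification: h(y, x) = γy^(γ−1)exp(bᵀx), so a one-unit increase in
covariate k multiplies the hazard by exp(b_k) at every response level.
Observations at or above a quality threshold y\* are right-censored at
y\* (δᵢ = 0); readings below it are events (δᵢ = 1). Ties y = y\* are
censored — conventions differ across survival software, so this is
stated explicitly. The event orientation is deliberately inverted
relative to clinical survival use: *low* responses are the events (e.g.
water-quality degradation), high responses survive.

Independence across sites is assumed conditional on covariates and
location; there is no residual spatial autocorrelation term. Coordinates
are treated as planar and distances are Euclidean. If coordinates are
supplied as geographic degrees, bandwidths inherit those units; the
package does not guess a projection, so bandwidth magnitudes are
dataset-dependent and not comparable across datasets.

## Global estimation

The censored log-likelihood
ℓ(φ) = Σᵢ δᵢ[log γ + (γ−1)log yᵢ + bᵀxᵢ] − yᵢ^γ exp(bᵀxᵢ),
φ = (γ, b), is maximized by Newton–Raphson with analytic gradient and
Hessian. Numerical safeguards, since the raw iteration diverges from
poor starts:

- initialization γ = 1, b₀ = log(Σδᵢ / Σyᵢ) (the exponential moment
  start), slopes 0; local fits are warm-started from the global optimum;
- step-halving line search (up to 30 halvings) until the log-likelihood
  is nondecreasing and γ stays positive;
- convergence when ‖∇ℓ‖∞ < 1e-6 or ‖Δφ‖∞ < 1e-8, at most 100 iterations;
- a singular/indefinite Hessian is ridge-stabilized (1e-8·I escalating
  tenfold to 1e-2) before a failure is declared;
- the term yᵢ^γ exp(bᵀxᵢ) is evaluated as exp(γ log yᵢ + bᵀxᵢ) to avoid
  overflow at large shapes.

var(φ̂) = −H(φ̂)⁻¹ supplies Wald standard errors. For γ < 1 the density
diverges at y = 0; the density function reports +inf there as a
sentinel, and likelihood code only ever evaluates y > 0.

## Spatial weighting and bandwidth

Local parameters φ(uᵢ) maximize Σⱼ wᵢⱼ ℓⱼ(φ) with adaptive Gaussian
weights wᵢⱼ = exp(−½(dᵢⱼ/aᵢ)²) (bi-square available). "Adaptive" means a
per-site scalar bandwidth aᵢ, chosen by minimizing
BIC(uᵢ) = −2ℓ(φ̂(uᵢ)) + K·log n with K = p + 2 and n the full sample
size, over 40 log-spaced candidates from the site's (p+2)-th
nearest-neighbour distance to twice the maximum pairwise distance, plus
the infinite candidate (all weights one, which reproduces the global fit
exactly). Ties break toward the larger bandwidth. A candidate is
eligible only if its weighted event mass Σⱼ wᵢⱼδⱼ reaches p + 2
(identification guard).

**Known limitation.** Because K and n in this BIC do not vary with the
candidate, the criterion cannot penalize locality itself: when the
per-observation log-likelihood contributions are predominantly negative
(typical for diffuse event-dominated data), shrinking the bandwidth
shrinks the magnitude of the weighted log-likelihood and the smallest
identified candidate tends to win; when contributions are positive
(sharply peaked fits, large γ), the direction reverses and large or
infinite bandwidths win. The identification guard bounds the collapse,
and in practice the resulting local fits still outperform the global
model on heterogeneous data (see the goodness-of-fit comparison below),
but the selected bandwidths should be read as "smallest defensible
neighbourhood", not as an unbiased heterogeneity scale. A variant that
replaces log n by log Σⱼwᵢⱼ is available
(`KernelConfig(bic_effective_n=True)`) and shares the same caveat.

## Inference

- **Global simultaneous test**: W = 2(ℓ_full − ℓ_null) against χ²(p),
  where the null model keeps shape and intercept only. The quadratic
  form B̂ᵀ[IF₂₂]⁻¹B̂ (slope block of the inverse information, dropping
  shape and intercept) is the large-sample equivalent.
- **Partial tests**: Q_k = b̂_k / se(b̂_k) against N(0,1), two-sided.
- **Similarity test** (local vs global): likelihood flavour
  G = 2Σᵢ(ℓᵢ(φ̂(uᵢ)) − ℓᵢ(φ̂)), where the global log-likelihood inside
  each gap is evaluated under the *same* spatial weights as the local
  fit — otherwise the per-site difference is not a nested comparison;
  quadratic-form flavour Σᵢ(B̂(uᵢ)−B̂)ᵀ[IF₂₂(uᵢ)]⁻¹(B̂(uᵢ)−B̂). Reference
  distribution χ²(n·p) in both cases.
- **Simultaneous local test**: Gw = 2Σᵢ(ℓᵢ(φ̂(uᵢ)) − ℓᵢ(φ̂₀(uᵢ))) with
  per-site weighted null fits, or Σᵢ B̂(uᵢ)ᵀ[IF₂₂(uᵢ)]⁻¹B̂(uᵢ); χ²(n·p).

The quadratic form is the default for both whole-model local tests: its
inputs are exactly the quantities the local fits tabulate. The two
flavours are *not* equivalent in finite samples: each local fit
optimizes p + 2 parameters against fixed global parameters, so the
likelihood flavour carries roughly (p+2) per-site optimism against a
χ²(n·p) reference and is considerably more aggressive, while the
quadratic form is damped by large local variances at small effective
sample sizes. They agree reliably only when heterogeneity is strong and
the sample is large enough for both to have power. The n·p degrees of
freedom follow the standard formulation for these tests; no
spatially-corrected effective-df adjustment is attempted.

- **Kolmogorov–Smirnov**: one-sample test of event-row responses against
  the fitted Weibull, using the *exact* finite-n distribution of D_n
  (`scipy.stats.kstwo`), not the asymptotic 1.36/√n rule — at n = 21 and
  α = 0.05 the critical value is 0.2872, versus 0.2963 asymptotically.
  Fitted parameters are treated as known (no Lilliefors correction), and
  censored rows do not enter the empirical CDF; both choices make the
  test conservative-leaning and are flagged here deliberately.

## Diagnostics and goodness of fit

- **VIF**: 1/(1−R²_k) from an intercept-included least-squares regression
  of covariate k on the others; flag threshold 10.
- **Glejser screen**: absolute residuals of an OLS fit of the raw
  response on the covariates, regressed back on the covariates; overall
  F with (p, n−p−1) df. OLS residuals are the default because the screen
  precedes any Weibull fit in the workflow; `residuals="wr_mean"`
  substitutes Weibull mean-regression residuals.
- **Model-level measures**: BIC = −2ℓ + K·log n with K = p+2;
  McFadden R² = 1 − ℓ_full/ℓ_null; MAPE = (100/n)Σ|yᵢ−μ̂ᵢ|/yᵢ against
  the *original* (uncensored) responses, since the response is fully
  observed and censoring is an analysis construct (an events-only flag
  exists); GCV = n·RSS/(n−K)² on the same mean-scale residuals — a
  hat-matrix GCV is not definable for this nonlinear model without
  further invention, so this deliberately simple surrogate is used.
  For the locally weighted model a single model-level log-likelihood is
  needed; it is defined as each observation's own-site contribution
  δᵢ log h(yᵢ,xᵢ; φ̂(uᵢ)) + log S(yᵢ,xᵢ; φ̂(uᵢ)), with K = p+2 — the
  minimal extension consistent with the global definitions. McFadden R²
  for the local model uses the global null fit as the shared baseline.
- **Backward elimination**: repeatedly drop the covariate with the
  largest Wald p-value above `alpha_stay` (default 0.10, so that
  borderline covariates significant at the 0.10 level can survive) and
  refit; the final model is the visited model with minimal BIC among
  those whose covariates all meet the stay rule.

## Interpretation

For a one-unit covariate increase at a site, the package reports four
ratios: R_S and R_F by direct evaluation of the survival and CDF models
before/after the increase at the site's own (yᵢ, xᵢ); R_h = exp(b̂_k)
exactly (proportional hazards); and R_μ = exp(−b̂_k/γ̂), which follows
from μ(x) = Γ(1+1/γ)exp(−bᵀx/γ). Site measures tabulate Ŝ, F̂, ĥ and μ̂
at each site's observed data with arithmetic regional averages, and
`curve_export` writes before/after curves over a response grid for
plotting.

## Synthetic data

The generator draws site coordinates uniformly in a box, covariates from
per-column normal/lognormal/uniform marginals, evaluates coefficient and
shape surfaces (constant, linear-in-coordinates, or radial bump) at
normalized coordinates, and draws responses by inverse CDF,
y = (−log(1−U)/λ)^(1/γ), before threshold censoring. It is deterministic
given a seed; cross-implementation bitwise equality is not promised, so
all downstream checks are statistical.

The study-scale fixture has 27 sites and 10 covariates whose marginals
match the descriptive statistics of a river-monitoring network
(iron ~0.31±0.25 ppm, temperature ~28.7±1.4 °C, BOD ~5.7±1.5 ppm, …),
threshold 6 ppm, constant shape 7, modest per-SD effects on the four
informative covariates (iron, phosphate, temperature, BOD; the iron
coefficient drifts linearly across the domain), and an intercept solved
analytically so the event probability at the mean covariate vector is
0.78 — matching a ~78% below-threshold fraction. Surfaces are
small-amplitude by default so local likelihoods remain identified at
27–100 sites.

What the generator does **not** emulate: residual spatial
autocorrelation, measurement error, covariate spatial structure, or the
real network's geography. Passing tests therefore demonstrate
correctness of the estimators and tests under the stated data-generating
process, not performance on real monitoring data.

Two named experiment configurations fix the study conditions for the
statistical checks: a global-truth design (shape 5, intercept −10,
slopes 0.8/−0.5, standard-normal covariates, threshold 8, ≈73% events)
used for recovery and test-size experiments at n = 400 and n = 200, and
a spatially varying design (intercept drifting ±1, first slope sweeping
−0.8…+0.8 across the domain) used for the local-vs-global comparison at
n = 60 with a 15-point bandwidth grid. Problem sizes (100 recovery
replicates, 500 size replicates, 20 comparison replicates) were chosen
so each check's Monte-Carlo error is small relative to its acceptance
band.

## Known limitations

- Per-site BIC bandwidth selection is degenerate in the directions
  described above; treat bandwidths qualitatively.
- The likelihood-flavour similarity/simultaneous statistics are
  anticonservative at n·p df; prefer the quadratic form, or interpret
  rejections conservatively.
- McFadden R² can leave [0, 1] for continuous-density likelihoods whose
  log-likelihood is positive; it is reported as defined.
- No interval/left censoring, no missing data handling, no frailty or
  time-varying effects, no mixed (partially global) local model.
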