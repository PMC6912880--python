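# Methods

This note documents the statistical procedures the package implements,
the defaults it ships, and the choices made where the design was open.

## Community indices

All abundance-based indices operate on **within-plot relative
abundances** `pᵢ = coverᵢ / Σ cover`. Percent covers are normalized
before any index is computed; this makes every index invariant to plot
size and to uniform rescaling of a plot's covers, which matters when
original surveys used different cover scales or plot sizes than the
resurvey. Species with zero cover in both plots of a comparison
contribute nothing (guaranteed by the formulas — no pseudo-counts are
used anywhere).

* **Morisita–Horn similarity** `C_MH = 2Σpᵢqᵢ/(Σpᵢ² + Σqᵢ²)`; temporal
  turnover is `d = 1 − C_MH ∈ [0, 1]`. Dominated by abundant species,
  insensitive to rare-species richness differences.
* **Hill–Simpson diversity** `D₂ = 1/Σpᵢ²` (effective number of
  species at order 2); satisfies `1 ≤ D₂ ≤ S` with equality at
  uniform abundances. Group-wise diversities (vascular / bryophyte /
  lichen / total) renormalize abundances within the group; a group
  absent from a plot yields a missing value, not zero, because "no
  lichens" is not "a very undiverse lichen community".
* **Multiple-assemblage turnover** of the N plots of a site uses the
  gamma/alpha Hill decomposition at order 2 with equal plot weights:
  `D_γ` from the arithmetic mean of the plots' relative abundances,
  `D_α = 1/meanⱼΣᵢpᵢⱼ²`, `D_β = D_γ/D_α`, overlap
  `C = (1/D_β − 1/N)/(1 − 1/N)`, turnover `1 − C`. This is the
  N-sample generalization of Morisita–Horn: 0 iff all plots share
  identical relative abundances, 1 iff all plots are pairwise
  disjoint. An alternative normalization can be swapped in by
  replacing this one function.
* **Bootstrap SE** for site-level beta: nonparametric resampling of
  plots with replacement (default 2,000 replicates); resamples with
  fewer than two distinct plots are redrawn because the statistic is
  undefined there. Published resurvey tables rarely state their SE
  estimator, so these SEs should be compared across sites within one
  analysis, not against externally printed values.

## CSR strategy profiles

Each vascular species carries (C, S, R) percentages summing to 100
(assigned upstream from a global calibration; the package treats them
as input data, it does not compute strategy coordinates from leaf
traits). The plot profile weights the coordinates by percent cover.
**Denominator choice**: only species that enter the numerator (vascular
plants with strategy data) enter the denominator by default, so the
three proportions always sum to 100 even on bryophyte-dominated plots.
The alternative — dividing by total plot cover including cryptogams —
is available via `denominator="total"`; it deflates all three
proportions and they no longer sum to 100.

Proportions are clamped to `[ε, 1−ε]` before the logit, with
`ε = 0.001` by default: small enough to move only boundary values,
large enough to keep the transform finite. The multivariate model fits
only logit C and logit S; R is fully determined as `100 − C − S` and
would make the likelihood degenerate.

Group cover changes (morphological groups; specified strategy classes
C, CR, R, SR, S, CS, CSR) are means over plots of the change in summed
absolute percent cover, with percentile 95% bootstrap CIs from
resampling plots (not species) — plots, not species, are the sampling
units of the design. With a single plot, or `reps = 1`, the interval
degenerates to the point estimate.

## Climate drivers

The growing season of a calendar year starts the day **after** the
first run of ≥ 10 consecutive days with daily mean temperature ≥ +5 °C
and ends the day after the first subsequent run of ≥ 10 consecutive
days below +5 °C; with no closing run the season extends to the year
end, and with no opening run the year has no season (thermal sum 0).
Only daily means are used — no min/max logic — and leap days count as
ordinary days.

The annual thermal sum is, by default, the Nordic effective temperature
sum `Σ max(T − 5, 0)` over the season (`gdd_mode="excess"`). The
literal reading "sum the daily temperatures that exceeded +5 °C" is
available as `gdd_mode="raw"`; the two differ by 5 °C × (number of
above-base days) and are both offered because published descriptions
are often ambiguous between them.

Between-survey changes are `Δ = slope × (year₁ − year₀)` with the slope
from OLS of the annual series on year, restricted to the survey
interval; at least three annual values are required. Multiplying by the
interval length makes sites with different sampling intervals
comparable in the same units (°Cd, mm/yr).

## Bayesian models and sampler

All models are normal linear regressions. Repeated-measures responses
(diversity per plot × period; logit CSR proportions) carry a plot
random intercept. The CSR model is bivariate: both the plot random
intercepts and the residuals of (logit C, logit S) have free 2×2
covariance matrices, so correlated strategy shifts and the negative
C–S compositional dependence are captured.

**Sampler.** The built-in sampler is a blocked Gibbs sampler with
conjugate priors; all full conditionals are exact, so there are no
divergences, mixing is fast, and a fit with zero observations samples
the prior exactly (this is tested). The backend is deliberately
pluggable: any sampler producing the same `PosteriorDraws` contract
(named draws per chain plus pointwise log-likelihood) can be
substituted; the test suite runs entirely on the built-in sampler.

**Priors** (defaults, scale-adapted, weakly informative):

| block | prior |
|---|---|
| slope βⱼ | Normal(0, (10·sd(y)/sd(xⱼ))²) |
| intercept | Normal(mean(y), (10·sd(y))²) |
| σ², τ² | Inverse-gamma(1, 0.01·var(y)) |
| 2×2 covariances | Inverse-Wishart(ν = 4, Ψ = diag(var(y_r))) |

The variance prior is proper but nearly flat above a small fraction of
var(y), so near-noiseless data can drive σ toward zero (the Bayesian
R² → 1 limit behaves correctly); conversely it adds only ~1
pseudo-observation of mass, so with realistic n the data dominate.
Conjugacy is why inverse-gamma/inverse-Wishart are used here rather
than half-t/LKJ forms: with exact conditional updates the sampler
needs no tuning, and at these weakly-informative scales the posterior
differences are negligible for the questions asked of these models.

Smooth sampling-time effects are represented by orthogonal polynomial
bases (degree ≤ 3) rather than penalized splines; with at most a
handful of distinct sampling times per study design, a spline has no
support to estimate more structure than a low-degree polynomial.

**Diagnostics.** Split R-hat and bulk ESS are computed (via ArviZ) for
every stored parameter; any R-hat above 1.01 raises a warning. Default
budget: 4 chains × 1,000 post-warmup draws after 1,000 warmup.

**PSIS-LOO.** Implemented from the published algorithm: per observation
the log importance ratios are `−log p(yᵢ|θ_s)`; the largest
`M = min(0.2·S, 3·√S)` ratios are replaced by expected order statistics
of a generalized Pareto distribution fitted to their exceedances
(empirical-Bayes profile fit with weak shape regularization), truncated
at the raw maximum weight; then
`elpd_i = log(Σ w_s·lik_s / Σ w_s)`, `elpd_loo = Σ elpd_i`,
`se = √(n·var(elpd_i))`. The Pareto shape k is reported per
observation with a warning threshold of 0.7. The implementation is
cross-checked in the tests against ArviZ's `psislw` and against exact
leave-one-out refits of a conjugate model.

**Bayesian R²** uses the σ-draws formulation
`R²_s = var(fitted_s) / (var(fitted_s) + σ²_s)` per draw.

## Synthetic generator

The generator emulates the study design the pipeline is built for:
4 subregions (MB, NBs, NBm, NBn) × (fertile herb-rich + infertile
heath) sites with 8–11 plots each (78 plots), original surveys
1957–1981 and resurveys 2013–2014 (sampling times 33–57 years).

* **Traits**: species split into a fertile and an infertile guild
  (120/100 species); vascular species draw (C, S, R) from
  guild-specific Dirichlet distributions — fertile guild concentrated
  toward C/R (α = (4, 1.5, 2.5)), infertile toward S
  (α = (1.2, 5, 1.8)) — and specified classes (C, CR, …, CSR) are
  derived from the coordinates. Morphological groups follow
  guild-typical frequencies (forbs dominate the fertile guild; dwarf
  shrubs, bryophytes and lichens the infertile one); lichens occur
  only in the infertile guild.
* **Communities**: a site holds ~40 species (85% own guild). A
  site-level base composition (Dirichlet, concentration 0.3 per
  species) and plot-level Dirichlet sampling (κ = 60 around the base)
  give the few-dominants / many-rares structure of boreal understorey
  data. Resurvey abundances mix each old plot toward a plot-specific
  target scattered (κ = 8) around a site-level resurvey draw, then
  apply an exponential abundance tilt per fertility class (default:
  fertile plots tilt from C toward S; infertile unchanged). The mixing
  weight per fertility class is calibrated by bisection against pilot
  simulations so the realized mean plot turnover hits the class target
  (defaults 0.36 fertile / 0.15 infertile, i.e. a −0.21 contrast);
  unattainable targets raise a calibration error. An optional
  replacement-rate knob adds previously absent species for
  high-turnover regimes.
* **Climate**: daily means follow an annual cosine (mean 1.5 °C,
  amplitude 13 °C, peak mid-July) plus a linear warming trend
  (0.03 °C/yr) and Gaussian noise (sd 3 °C); daily precipitation is
  Gamma(0.7, 2.6) mm (≈ 660 mm/yr). These reproduce boreal growing
  seasons of roughly 120–160 days and thermal-sum changes of order
  +150…+250 °Cd over 40–55 years.

**What the generator does not emulate**: real spatial structure,
species-specific temporal autocorrelation, observer error, and —
importantly — the full between-plot heterogeneity of field data.
Synthetic within-class turnover spreads are narrower than real
resurvey data, so model fits on synthetic data reach higher R² than
field analyses typically do; passing recovery tests demonstrates the
estimators are correct and calibrated, not that field effect sizes
will be as cleanly estimable.

## Problem sizes and determinism

Default analysis scale is the full design (78 plots, ~220 species,
2,000 bootstrap replicates, 4×1,000 MCMC draws), which runs in well
under a minute. The test suite uses reduced sizes (hundreds of
bootstrap replicates, 1–2 chains of a few hundred draws, 20–50 seed
replicates for coverage studies) chosen so each recovery check still
has the power to detect a broken estimator. All randomness flows from
a single seed through `numpy.random.SeedSequence` spawning; identical
inputs and seed give byte-identical output files.

## Known limitations

* Duplicate (plot, species) rows in input tables are rejected, not
  summed; taxonomic harmonization (genus pooling, species merges) is
  the user's upstream responsibility.
* The multiple-assemblage overlap uses equal plot weights; size- or
  abundance-weighted variants are not implemented.
* Incidence-based indices, Chao-type richness corrections, ordination
  and spline smoothers are out of scope.
* The Gibbs sampler covers normal-error linear models with at most a
  bivariate response; other likelihoods would need a new backend
  honoring the `PosteriorDraws` contract.
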