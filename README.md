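# resurvey

Analysis toolkit for **long-term vegetation resurveys**: paired plot
surveys of the same understorey communities taken decades apart. It is
aimed at community ecologists asking how much, and in what direction,
plant communities changed between an original survey and a resurvey —
and whether site properties such as fertility modulate that change.

The package covers the full analysis chain:

* **Temporal turnover** of each plot, `d = 1 − C_MH`, where the
  Morisita–Horn similarity of the two periods' relative abundances
  `p, q` is

  `C_MH(p, q) = 2 Σᵢ pᵢqᵢ / (Σᵢ pᵢ² + Σᵢ qᵢ²)`.

  The index is abundance-weighted, so it is robust to rare-species
  richness differences caused by unequal plot sizes or observers.
* **Effective species numbers** (Hill number of order 2, the effective
  number of species of Simpson diversity): `D₂ = 1 / Σᵢ pᵢ²`, computed
  per plot for vascular plants, bryophytes, lichens and all species.
* **Within-site beta diversity** via the multiple-assemblage
  generalization of Morisita–Horn: with equal plot weights,
  `D_γ = D₂(pooled)`, `D_α = 1 / meanⱼ Σᵢ pᵢⱼ²`, `D_β = D_γ / D_α`,
  overlap `C = (1/D_β − 1/N)/(1 − 1/N)`, and turnover `β = 1 − C`.
  `Δβ = β_new − β_old` is positive when a site heterogenized and
  negative when it homogenized. Plot-bootstrap standard errors.
* **CSR strategy profiles**: community-weighted Grime competitor /
  stress-tolerator / ruderal proportions,
  `propX = Σᵢ coverᵢ·Xᵢ / Σᵢ coverᵢ` over vascular species with
  strategy data, logit-transformed for modeling; plus absolute cover
  changes of morphological and specified strategy groups with
  bootstrap CIs.
* **Climate drivers**: growing-season detection (day after ten
  consecutive daily means ≥ +5 °C, closing on ten consecutive < +5 °C),
  thermal sums `Σ max(T − 5, 0)` in degree-days, annual precipitation,
  and between-survey deltas `Δ = slope × years` from OLS trends.
* **Bayesian inference**: normal linear regressions of turnover and
  log1p diversity (plot random intercepts for repeated measures), a
  bivariate hierarchical model of (logit C, logit S) with free 2×2
  residual and random-intercept covariances, PSIS-LOO model comparison,
  and Bayesian R². A built-in conjugate Gibbs sampler keeps fits fast
  and exactly reproducible by seed.
* **Synthetic data**: a generator that emulates the paired-survey study
  design (4 subregions × fertile/infertile sites, 78 plots, 33–57 year
  intervals) with a calibrated turnover contrast, guild-structured CSR
  traits and daily climate with a warming trend — so every stage is
  testable with known ground truth.

## Worked example

```sh
python examples/bayesian_turnover.py
```

generates a synthetic study, fits three turnover models and prints:

```
                      model  elpd_loo  se_elpd  d_elpd  se_diff  n_high_k
       turnover ~ fertility    101.01     6.42    0.00     0.00         0
turnover ~ fertility + time    100.87     6.22   -0.14     1.02         0
               turnover ~ 1     69.73     4.92  -31.28     6.40         0

fertility effect on turnover: -0.145 [-0.173, -0.116] (95% CI)
Bayesian R^2 (median): 0.56
```

Reading: the model with site fertility dominates the intercept-only
model by 31 elpd units, while adding sampling time gains nothing — the
fertility contrast, not the interval length, carries the signal. The
negative coefficient says infertile plots turned over about 0.15 less
(on the 0–1 dissimilarity scale) than fertile plots in this simulated
study; R² is the share of turnover variance the fitted model explains.

Other entry points: `examples/turnover_basics.py`,
`examples/beta_diversity_change.py`, `examples/csr_strategies.py`,
`examples/climate_trends.py`, `examples/full_pipeline.py`; or from the
shell,

```sh
resurvey simulate --seed 1 --out data/
resurvey run --config cfg.yaml
resurvey turnover|csr|climate ...
```

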