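# ecodiff

Hierarchical ecological-diffusion modelling of recolonizing populations.

`ecodiff` is built for the situation where a predator population, reseeded
at a handful of release sites, grows and spreads through a heterogeneous
nearshore landscape while being observed only through imperfect aerial
surveys. It couples a mechanistic spread model to a detection-aware
observation model and fits both by MCMC, so that movement, density
dependence, growth and detection are estimated together. The motivating
system is a sea otter population recolonizing a fjord archipelago from seven
translocation sites, monitored for decades by strip-transect, distribution
and photographic surveys.

## The model

Population intensity λ(s,t) follows logistic **ecological diffusion**

∂λ/∂t = ∇²(δ(s) λ) + γ λ (1 − λ/K(s)),

with motility δ(s) = exp(x(s)ᵀβ) (low δ = long residence time; covariates:
shallow-depth indicator, distance to shore, slope×depth, shoreline
complexity, distance to towns, two management-area indicators) and local
density dependence K(s) = exp(w(s)ᵀα). The initial state is a sum of J
Gaussian kernels at the release epicenters with scales θⱼ and spreads κⱼ.
The PDE is solved by homogenized sparse finite differences: coefficients are
upscaled to a coarse grid (harmonic-mean δ̄, averaged 1/(δK)), stepped with
an implicit diffusion / exact logistic split, and downscaled as λ = c/δ.

Observations are an N-mixture hierarchy: true abundance
N_{i,t} ~ NB(λ_{i,t}, τ) and counts y_{i,t} ~ Binomial(N_{i,t}, p_t), with
detection p_t informed by intensive search units (recounted groups) and, in
photographic-survey years, an informative Beta prior. A
Metropolis-within-Gibbs sampler (random-walk blocks for the process
parameters — one PDE solve per proposal — exact conditional draws of the
latent N, conjugate Beta draws of p_t) returns posterior means and credible
intervals, plus derived quantities: asymptotic spread-rate maps
(2√(δ̄γ) for steep fronts, δ̄/κ² + γκ² for flat ones), total-abundance time
series, and posterior predictive checks.

There is no bundled field data; a first-class synthetic-study generator
produces landscapes, truth and all three survey types with the statistical
structure the analysis assumes, so the whole pipeline is testable end to
end.

## Worked example

```python
import ecodiff as ed

# a complete synthetic study: landscape, truth, three survey types
study = ed.generate_study(seed=1)
print(len(study.surveys.counts), "count records,",
      len(study.surveys.isu), "ISU records")
# 2334 count records, 23 ISU records

totals = study.truth.series.total_abundance_intensity()
print("expected abundance, years 0/10/19:", totals[[0, 10, 19]].round(1))
# expected abundance, years 0/10/19: [ 47.1 143.5 171.1]

# fit the hierarchical model
priors = ed.PriorSpec.for_study(
    study.truth.params.theta, study.truth.params.kappa_m, photo_years=(19,))
cfg = ed.MCMCConfig(n_iter=3600, n_burn=1800, n_chains=1, seed=0, dt_days=5.0)
chains = ed.run_mcmc(study.surveys, study.landscape,
                     study.truth.params.epicenters, priors, cfg)
print(ed.summarize(chains, level=0.90).loc[["gamma", "tau"]].round(3))
#             lower   mean  upper
# parameter
# gamma       0.191  0.264  0.344
# tau         0.022  0.029  0.036
```

The `gamma` row is the posterior 90% interval for the intrinsic growth rate
(truth 0.29 in this study); `tau` is the negative-binomial dispersion
(truth 0.03 — small values mean heavily clustered counts). Spread rates and
abundance series then come from `ed.spread_rate_map`, `ed.total_abundance`
and `ed.posterior_predictive_check`, or from the CLI:

```bash
ecodiff simulate-study --seed 1 --out study/
ecodiff fit --data study/ --iters 1200 --burn 600 --chains 1 --seed 0 --out fit/
ecodiff derive --data study/ --chains fit/chains.csv --out derived/
# spread rates (km/yr): min 1.17, median 2.22, max 4.66
```

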