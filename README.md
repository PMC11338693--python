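# martendyn

Population dynamics of pine martens (*Martes martes*) from winter snow-track
surveys: effort-corrected abundance indices, density-dependence diagnosis,
interpolated prey surfaces, landscape covariates, and Bayesian mixed models —
with a synthetic study-system generator so the whole analysis can be
validated end to end against known ground truth.

## The scientific problem

Boreal mesocarnivores such as the pine marten eat cyclic microtine rodents
(voles and lemmings), but whether marten populations *track* those 3–5 year
cycles is unclear. Given a decade of volunteer snow-transect surveys (track
counts with survey effort), municipality-level rodent presence/absence
monitoring, and landscape layers (elevation, mature spruce forest,
agricultural land), the questions are:

1. Is the marten population directly density-dependent (order-1 feedback) or
   delayed/cyclic (order ≥ 2)?
2. How do rodent abundance, elevation, their interaction, snow depth and
   habitat densities affect the population growth rate and abundance?

## The method

**Abundance index.** For each transect visit,

```
index = tracks / (transect length [km] × days since last snowfall)
```

an effort-corrected rate in tracks·km⁻¹·day⁻¹. Transects are clustered by
proximity (k-means, ≈10 per group) and the group-mean index forms annual
series *N_t*; the realized growth rate is *R_t = ln(N_t / N_{t−1})*.

**PRCF.** The Partial Rate Correlation Function regresses *R_t* on lagged
log densities: PRCF(1) is the correlation of *R_t* with *X_{t−1} = ln N_{t−1}*,
and PRCF(d) is the partial correlation of *R_t* with *X_{t−d}* controlling
for the intermediate lags. The smallest lag with a significantly negative
coefficient — judged against Bartlett's ±2/√n band — estimates the order of
density-dependent feedback.

**Prey surface.** The proportion of rodent survey lines per municipality
with a detection is interpolated from municipality centroids by inverse
distance weighting (power 2, 12 neighbours) onto a 1.9 × 3.0 km raster and
sampled at transect centroids; January tracks of year *t* pair with the
previous autumn's surface. A snap-trap series (catches/100 trap-days)
validates the index.

**Covariates.** Mean elevation over a 7.17 km² home-range grid, Gaussian
kernel densities of mature-spruce and agricultural patches (size-weighted),
and snow depth; all z-standardized and screened for collinearity (|r| < 0.6).

**Models.** Two Bayesian GLMMs with Normal(0, 2²) priors on intercepts and
slopes, fitted by MCMC with R̂ < 1.01 convergence checks, 80% equal-tailed
credible intervals, and posterior predictive checks:

- growth: `R_gt ~ Normal(β0 + β'z + u_g, σ²)`, group intercepts
  `u_g ~ N(0, σ_g²)`;
- abundance: `tracks ~ NegBin(μ, θ)` with
  `log μ = log(length) + log(days) + δ0 + δ'z + v_year`, variance μ + μ²/θ.

## Worked example

Run the full pipeline on a small synthetic study system (150 transects,
8 municipalities, 12 survey winters):

```python
from martendyn import SimConfig, RunConfig, run_all

cfg = RunConfig(
    sim=SimConfig(n_transects=150, n_municipalities=8,
                  region_width_km=80, region_height_km=120,
                  n_spruce_patches=120, n_agri_patches=90, seed=42),
    chains=2, iterations=2000, warmup=1000, seed=42,
)
report = run_all(cfg)
```

which prints (via the report dictionary):

```
PRCF: 8 of 15 series place their most negative coefficient at lag 1 (direct density dependence)
rodent index vs snap traps: r^2 = 0.871 (p = 0.0000)
abundance model (delta, 80% CRI):
  delta_intercept              -2.084 [-2.223, -1.946] *
  delta_rodent_index           +0.408 [+0.325, +0.499] *
  delta_elevation              +0.372 [+0.291, +0.454] *
  delta_rodent_x_elevation     +0.083 [+0.008, +0.160] *
  delta_snow                   +0.455 [+0.382, +0.526] *
  delta_spruce_density         +0.393 [+0.331, +0.454] *
  delta_agri_density           -0.134 [-0.224, -0.040] *
```

A `*` marks an 80% credible interval that excludes zero — read as evidence
of an effect. The generating truth for this world was
δ = (−2.15, 0.566, 0.425, 0.160, 0.463, 0.369, −0.129): the fitted means
recover sign and magnitude of every coefficient through the full pipeline
(IDW prey surface, home-range elevation grid, kernel densities), with the
rodent slope attenuated because the detection-proportion surface is a proxy
for the latent abundance the counts were generated from.

The same stages are available as a CLI (`martendyn simulate | indices |
prcf | rodent-surface | covariates | fit | run-all | validate`); see
`martendyn --help`.

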