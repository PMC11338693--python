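# Methods

This note documents the models, the synthetic study system, the numerical
choices and the known limitations of `martendyn`. Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Abundance index and grouping

The per-visit index `tracks / (length_km × days_since_snow)` assumes track
accumulation is proportional to both the transect length and the number of
days since the last track-erasing snowfall; it is a relative activity
index, not a density estimate. Both effort terms must be strictly positive
(`days_since_snow = 0` leaves the index undefined and is rejected at
validation; the survey design implies at least one accumulation day).

Because individual transects are not surveyed every winter, transects are
clustered by proximity into groups of about ten (k-means on the unique
transect centroids, k = round(n/10), fixed seed, transects sorted by id
before fitting so ties are deterministic) and the group-mean index forms
the time series. Years in which no group member was surveyed are gaps;
series are split at gaps and only consecutive runs with more than
`min_steps = 3` observations enter the feedback diagnosis.

Growth rates are computed on the group-mean series (not averaged over
per-transect rates): this matches the series the PRCF consumes and avoids
taking logs of per-transect zeros. Zero handling before the log is
configurable; the default adds half the smallest positive value of the
series to every observation, a standard small-sample continuity
correction. Alternatives (`drop`, fixed constant) are provided.

## PRCF

With `X_t = ln N'_t` and `R_t = X_t − X_{t−1}`, PRCF(1) is the Pearson
correlation of `R_t` with `X_{t−1}`; for lag d ≥ 2 the partial correlation
of `R_t` with `X_{t−d}` given the intermediate lags is computed by
correlating the residuals of the two controlling OLS regressions — a form
that stays numerically stable for the short (4–12 point) series this
diagnostic is built for. The matrix-inversion form of the partial
correlation is kept as an independent oracle in the tests (agreement to
1e−10).

Significance uses Bartlett's approximate band ±2/√n with n the length of
the consecutive series. `max_lag` defaults to ⌊length/3⌋ capped at 5;
requests beyond what the series supports are truncated with a warning.
Two classifications are reported per series: the smallest lag whose
coefficient is negative and exceeds the band (the inferred order), and the
lag of the most negative coefficient (`argmin_lag`, the basis of the
majority count).

**Calibration caveat.** Bartlett's band presumes a stationary series.
For a series that is close to a pure random walk, the lag-1 coefficient is
the Dickey–Fuller-type statistic and is biased negative in finite samples;
Monte-Carlo calibration in the acceptance suite shows ≈28% band exceedance
at lag 1 (all negative) versus ≈5% at lags 2–5 for random-walk nulls of
length 200. In practice this means the PRCF over-detects *direct* density
dependence for near-random-walk series; the order-2-and-above
classification, which carries the cyclicity conclusion, is correctly
calibrated.

## Rodent prey surface

The municipality index is the proportion of survey lines with a rodent
detection — a conservative abundance proxy bounded in [0, 1]. IDW
interpolation uses power 2 over the 12 nearest municipality centroids
(the neighbourhood rule of the original GIS tool is unpublished; 12
nearest, no sector constraints, configurable). IDW is an exact
interpolator at data points (cells within 1e−9 km of a centroid take the
centroid's value) and never extrapolates outside the data range. The
default raster is 1.9 km × 3.0 km, row-major from the north-west origin
with half-open cell intervals; rasters are exchanged as ESRI ASCII grids,
using the GDAL dx/dy header extension for rectangular cells. Extraction
takes the containing cell's value with no resampling; points outside the
extent snap to the nearest cell with a warning.

The pairing convention everywhere is: January tracks of year *t* ↔ autumn
rodent surface of year *t* − 1 (prey availability precedes the winter
survey). The snap-trap validation reports Pearson r, r² and the two-sided
p-value from the exact t-transform with n − 2 degrees of freedom.

## Landscape covariates

Elevation: a square grid of cell area 7.17 km² (the average marten home
range; side √7.17 ≈ 2.678 km) is anchored at the DEM's south-west corner;
each cell averages the DEM pixels whose centres fall inside, and each
transect takes its containing cell's mean. Edge sliver cells narrower than
one DEM pixel fall back to the pixel under the point. Habitat densities:
size-weighted planar Gaussian kernel density of patch centres, default
bandwidth 5 km (the source cartography's kernel and bandwidth are not
published; the synthetic truth uses the same kernel so the pipeline is
internally consistent). The surface integrates to the total patch size.

Covariates are z-standardized (sample SD, n − 1) with the constants stored
for inverse transforms; standardization is computed over the rows entering
each model, not globally. Pairwise Pearson correlations among the
continuous covariates are screened at |r| ≥ 0.6.

## Bayesian GLMMs

Priors: Normal(0, 2²) on every intercept and slope; half-Normal(0, 2) on
the residual and random-effect SDs; Exponential(1) on the inverse NB
dispersion 1/θ. Positive parameters are sampled on the log scale with the
Jacobian included. The two effort offsets are summed into one offset term
(mathematically identical to entering both). Effects are reported with
posterior means, 80% equal-tailed credible intervals and an excludes-zero
flag; no p-values.

**Sampling.** Both models are explored with ensembles of
Metropolis–Hastings walkers (via `emcee`), with `chains` independent
ensembles treated as MCMC chains so split-R̂ and bulk ESS (via `arviz`)
compare genuinely independent runs. The proposal machinery is built
around a Laplace approximation at the posterior mode:

- the mode is found by bounded L-BFGS (log-scale parameters constrained to
  [log 0.05, log 20] so the optimizer cannot slide into the zero-variance
  density spike of a centered hierarchy, a region of diverging density but
  vanishing mass);
- the Hessian (central finite differences, vectorized) gives the proposal
  covariance, with a floor of 0.15 on the log-scale coordinates' proposal
  SD in case the Hessian is pinched against an optimisation bound;
- 80% of proposals are independence draws from a multivariate-t (df 8,
  scale ×1.3) centred at the mode — for these near-Gaussian posteriors
  the chain then decorrelates in a handful of steps; the rest are
  covariance-scaled Gaussian random-walk steps;
- hierarchical count models additionally get two tailored joint moves:
  a funnel rescale (log σ′ = log σ + ε, v′ = v·e^ε, Jacobian e^{Gε}) and a
  likelihood-invariant intercept shift (δ0′ = δ0 + ε, v′ = v − ε), which
  directly mix the two soft directions that dominate the autocorrelation
  time of such posteriors.

For the normal growth model the group intercepts are marginalized exactly
(per-group covariance σ²I + σ_g²J via the Woodbury identity), the sampler
explores only the fixed effects and two scales, and the intercepts are
reconstructed afterwards from their exact Gaussian conditionals — so a
model with ~60 groups mixes as fast as a 7-parameter one.

Defaults are 4 chains × 6000 iterations (3000 warm-up); each ensemble's
chain is assembled by thinning the step-major post-warmup draws with a
stride that is not a multiple of the walker count, so consecutive thinned
draws come from different walkers while split-R̂ still compares early
versus late sampling. Non-convergence (any R̂ ≥ 1.01) sets an explicit
flag and emits a warning — never a silent failure. Random-effect
parameterization is centered when levels carry ≥ 50 observations and
non-centered otherwise (overridable). The sampler is validated (R̂ < 1.01,
ESS > 400, parameter recovery, prior-only marginals, conjugate closed
forms, offset and standardization contracts) for data sizes from roughly
one hundred observations per random-effect level upwards; far below that,
expect the convergence flag to trip.

Posterior predictive checks simulate replicate responses at thinned
posterior draws (including the drawn random-effect values) and report the
observed statistic's quantile position for the mean, SD and — for counts —
the proportion of zeros.

## Synthetic study system

The generator emulates the monitoring design the pipeline assumes, with
every stochastic quantity derived from one seed (identical configurations
give identical worlds):

- region 130 × 210 km (≈27,000 km²) with a south–north elevation gradient
  (base 150 m, 5 m/km northing, smoothed noise SD 150 m) standing in for
  the boreal lowland-to-mountain productivity gradient;
- 19 municipalities as Voronoi cells of random centroids;
- per-municipality rodent log-abundance from a second-order log-linear
  (Gompertz-type) process, default (a0, b1, b2) = (0, −0.1, −0.6) with
  noise SD 0.4, giving 3–6 year cycles; cycle amplitude is scaled by
  (1 + 0.3 · standardized elevation) so fluctuations are stronger at
  higher elevations;
- 593 transects placed uniformly, each surveyed in a given winter with
  probability 0.47 (reproducing the observed mean of ≈278 surveys per
  year); length ~ N(2.93, 0.51²) km truncated above 0.5, days since
  snowfall ~ N(3.70, 1.65²) truncated at 1 — the survey design's observed
  effort moments;
- snow depth 20 + 0.02·elevation + N(0, 12²) cm, a coupling weak enough
  that the elevation–snow correlation stays under the 0.6 collinearity
  screen, as in the real survey design;
- spruce patches uniform over the region, agricultural patches
  concentrated in the southern lowlands (exponential northing decay),
  sizes log-normal;
- track counts from the negative-binomial offset model with the
  published-scale coefficient vector δ = (−2.15, 0.566, 0.425, 0.160,
  0.463, 0.369, −0.129), dispersion θ = 1.5 and year-effect SD 0.2; the
  intercept is set so mean counts per visit are a few tracks;
- rodent line surveys: 80 lines per municipality per autumn, each
  detecting presence with probability logistic(1.5 · centred log
  abundance); the snap-trap series is a log-normally perturbed
  (SD 0.15) exponential transform of the highest-elevation municipality's
  latent abundance.

What the generator does *not* emulate: spatial autocorrelation of counts
beyond what the smooth covariate surfaces induce, observation error in the
track-to-index mapping (detection is folded into the NB noise),
zero-inflation, inter-annual weather, and movement mechanics. Passing
tests therefore show that the pipeline recovers the generating process
*under its own model family and a monotone prey proxy*; they do not
certify behaviour under model misspecification.

In the end-to-end pipeline the rodent covariate is the IDW-interpolated
detection proportion — a bounded, monotone proxy of the latent log
abundance that generated the counts — so its fitted slope is attenuated
relative to the generating value while the directly-measured covariates
(elevation, snow, habitat densities) recover theirs closely. The
acceptance script therefore reports parameter recovery both ways: exactly
(fitting the generator's own model frame at n = 3000) and through the full
proxy pipeline.

## Problem sizes and reproducibility

The test suite and the acceptance script run everything at desk scale on
one CPU: PRCF Monte-Carlo batches of 200–500 series, GLMM fits with
2 independent ensembles on 1000–3300 rows, and the full default study
system (593 transects, 12 winters). The pipeline's `RunConfig.seed` drives
transect placement, rodent dynamics, count noise, clustering and every
sampler, so a rerun reproduces all numeric outputs including the posterior
draws bit for bit.
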