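"""Synthetic boreal study system with known ground truth.

Emulates the monitoring design the downstream pipeline assumes: a planar
region with a south-north elevation/productivity gradient, municipalities
(Voronoi cells) whose microtine rodent populations follow cyclic
second-order log-linear dynamics with elevation-dependent amplitude, a
network of snow transects surveyed each January with realistic effort
(length ~ N(2.93, 0.51^2) km truncated above 0.5, days since snowfall ~
N(3.70, 1.65^2) truncated at 1), and pine marten track counts drawn from a
negative-binomial model with log-effort offsets and year random effects.
Rodent line-transect surveys (presence/absence per line) and a snap-trap
validation series for one high-elevation municipality are generated from
the same latent rodent abundances.

Every stochastic quantity derives from the single ``SimConfig.seed``, so an
identical configuration reproduces the world exactly; the generating
parameters are kept in ``SyntheticWorld.truth`` so estimation stages can be
checked against ground truth.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import ndimage
from shapely.geometry import MultiPoint, Point, box, mapping
from shapely.ops import voronoi_diagram

from .landscape import patch_kernel_density, z_standardize
from .rodent_surface import GridSpec, Raster

# covariate order of the abundance model's slope vector (after the intercept)
COVARIATE_ORDER = (
    "rodent_index",
    "elevation",
    "rodent_x_elevation",
    "snow",
    "spruce_density",
    "agri_density",
)

# published-scale coefficient vector used as the default generating truth:
# intercept then slopes in COVARIATE_ORDER
DEFAULT_TRUE_DELTA = (-2.15, 0.566, 0.425, 0.160, 0.463, 0.369, -0.129)


@dataclass
class SimConfig:
    """Generating parameters of the synthetic study system."""

    region_width_km: float = 130.0
    region_height_km: float = 210.0
    n_municipalities: int = 19
    n_transects: int = 593
    years: tuple[int, int] = (2003, 2014)
    survey_prob: float = 0.47  # annual chance a transect is surveyed (mean ~278/593)

    # elevation field (metres): south-north gradient plus smoothed noise
    elevation_base_m: float = 150.0
    elevation_gradient: float = 5.0   # m per km northing
    elevation_noise_sd: float = 150.0
    dem_cell_km: float = 2.0

    # rodent log-abundance dynamics (cyclic second-order by default)
    rodent_ar_params: tuple[float, float, float] = (0.0, -0.1, -0.6)
    rodent_noise_sd: float = 0.4
    amplitude_elevation_slope: float = 0.3

    # rodent observation model
    n_lines_per_municipality: int = 80
    detection_slope: float = 1.5
    snap_trap_noise_sd: float = 0.15

    # marten track-count model
    true_delta: tuple[float, ...] = DEFAULT_TRUE_DELTA
    nb_dispersion: float = 1.5
    year_effect_sd: float = 0.2
    group_effect_sd: float = 0.2

    # landscape patches
    n_spruce_patches: int = 400
    n_agri_patches: int = 300

    seed: int = 0

    def validate(self) -> None:
        if self.region_width_km <= 0 or self.region_height_km <= 0:
            raise ValueError("region must have positive area")
        if self.years[1] - self.years[0] + 1 < 5:
            raise ValueError("years must span at least 5 years")
        if self.n_transects < self.n_municipalities:
            raise ValueError("need at least one transect per municipality")
        for name in ("rodent_noise_sd", "nb_dispersion", "year_effect_sd", "group_effect_sd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if len(self.true_delta) != 1 + len(COVARIATE_ORDER):
            raise ValueError(f"true_delta must have {1 + len(COVARIATE_ORDER)} entries")

    @property
    def year_range(self) -> np.ndarray:
        return np.arange(self.years[0], self.years[1] + 1)

    @property
    def rodent_years(self) -> np.ndarray:
        # autumn rodent index of year t-1 pairs with January tracks of year t
        return np.arange(self.years[0] - 1, self.years[1])


@dataclass
class SyntheticWorld:
    """A generated study system plus the parameters that generated it."""

    config: SimConfig
    transects: pd.DataFrame          # one row per surveyed transect-year
    municipalities: pd.DataFrame     # id, centroid, polygon (shapely), elevation
    rodent_truth: pd.DataFrame       # municipality_id, year, log_abundance
    rodent_surveys: pd.DataFrame     # municipality_id, year, lines_total, lines_with_detection
    snap_traps: pd.DataFrame         # year, catches_per_100_trapdays
    patches: pd.DataFrame            # x_km, y_km, size, class
    elevation: Raster
    truth: dict


def simulate_population_series(
    order: int,
    params: tuple[float, float, float],
    noise_sd: float,
    length: int,
    seed: int | None = None,
    x0: float | None = None,
    rng: np.random.Generator | None = None,
    burn_in: int = 50,
) -> np.ndarray:
    """Gompertz-type log-linear population series.

        x_t = a0 + (1 + b1) x_{t-1} + b2 x_{t-2} + eps_t,  eps ~ N(0, noise_sd^2)

    ``order`` 1 requires b2 = 0 (direct density dependence only); order 2
    admits the delayed feedback that produces multi-annual cycles.  When
    ``x0`` is given the series starts there with no burn-in (deterministic
    skeletons for tests); otherwise it starts at the deterministic
    equilibrium and ``burn_in`` initial steps are discarded so the returned
    series is approximately stationary.
    """
    a0, b1, b2 = (float(p) for p in params)
    if not np.isfinite([a0, b1, b2]).all():
        raise ValueError("autoregression parameters must be finite")
    if order == 1 and b2 != 0.0:
        raise ValueError("order-1 dynamics require b2 = 0")
    if order not in (1, 2):
        raise ValueError("order must be 1 or 2")
    if length < 10:
        raise ValueError("length must be >= 10")
    roots = np.roots([1.0, -(1.0 + b1), -b2])
    if np.abs(roots).max() > 1.0 + 1e-9:
        warnings.warn(
            f"characteristic roots {roots} outside the unit circle: series may diverge",
            stacklevel=2,
        )
    if rng is None:
        rng = np.random.default_rng(seed)

    if x0 is not None:
        start = float(x0)
        n_burn = 0
    else:
        denom = -(b1 + b2)
        start = a0 / denom if abs(denom) > 1e-12 else 0.0
        n_burn = burn_in
    total = length + n_burn
    x = np.empty(total + 1)
    x[0] = start
    prev2 = start
    eps = rng.normal(0.0, noise_sd, size=total) if noise_sd > 0 else np.zeros(total)
    for t in range(1, total + 1):
        x[t] = a0 + (1.0 + b1) * x[t - 1] + b2 * prev2 + eps[t - 1]
        prev2 = x[t - 1]
    out = x[1:] if x0 is None else x[: length]
    if x0 is not None:
        return out.copy()
    return out[n_burn : n_burn + length].copy()


def _truncated_normal(rng, mean, sd, lower, size):
    """Rejection-sampled truncated normal (lower bound only)."""
    out = rng.normal(mean, sd, size=size)
    bad = out <= lower
    while bad.any():
        out[bad] = rng.normal(mean, sd, size=int(bad.sum()))
        bad = out <= lower
    return out


def _voronoi_municipalities(centroids: np.ndarray, width: float, height: float) -> list:
    region = box(0.0, 0.0, width, height)
    cells = voronoi_diagram(MultiPoint([Point(p) for p in centroids]), envelope=region)
    polys = [None] * len(centroids)
    for cell in cells.geoms:
        clipped = cell.intersection(region)
        for i, p in enumerate(centroids):
            if cell.covers(Point(p)):
                polys[i] = clipped
                break
    if any(p is None for p in polys):  # pragma: no cover - degenerate geometry
        raise RuntimeError("Voronoi cell assignment failed")
    return polys


def build_world(config: SimConfig) -> SyntheticWorld:
    """Generate the complete synthetic study system from a configuration.

    Deterministic given ``config`` (including its seed).  The returned
    world contains surveyed transect-year records with true covariates and
    simulated track counts, the latent rodent series, rodent line-transect
    surveys, a snap-trap validation series, habitat patches and the DEM.
    """
    config.validate()
    w, h = config.region_width_km, config.region_height_km
    ss = np.random.SeedSequence(config.seed)
    (
        s_mun, s_elev, s_rodent, s_transects, s_patches, s_tracks, s_surveys
    ) = (np.random.default_rng(c) for c in ss.spawn(7))

    # --- municipalities: Voronoi cells of random centroids -----------------
    margin = 0.05
    centroids = np.column_stack(
        [
            s_mun.uniform(margin * w, (1 - margin) * w, config.n_municipalities),
            s_mun.uniform(margin * h, (1 - margin) * h, config.n_municipalities),
        ]
    )
    polygons = _voronoi_municipalities(centroids, w, h)

    # --- elevation DEM: gradient in northing + smoothed noise --------------
    grid = GridSpec.from_extent(0.0, 0.0, w, h, config.dem_cell_km, config.dem_cell_km)
    dem = grid.empty()
    _, Y = dem.cell_centers()
    noise = s_elev.normal(0.0, 1.0, size=Y.shape)
    smooth = ndimage.gaussian_filter(noise, sigma=3.0, mode="nearest")
    sd = smooth.std()
    smooth = smooth / sd * config.elevation_noise_sd if sd > 0 else smooth
    dem.values = config.elevation_base_m + config.elevation_gradient * Y + smooth
    dem.values = np.maximum(dem.values, 0.0)

    mun_elev = np.array(
        [
            dem.values[dem.cell_index(cx, cy, clamp=True)]
            for cx, cy in centroids
        ],
        dtype=float,
    )
    municipalities = pd.DataFrame(
        {
            "municipality_id": [f"M{i + 1:02d}" for i in range(config.n_municipalities)],
            "centroid_x_km": centroids[:, 0],
            "centroid_y_km": centroids[:, 1],
            "elevation_m": mun_elev,
            "polygon": polygons,
        }
    )

    # --- rodent dynamics: cyclic log-abundance, amplitude grows with elevation
    if config.n_municipalities > 1 and mun_elev.std(ddof=1) > 0:
        z_elev_mun = (mun_elev - mun_elev.mean()) / mun_elev.std(ddof=1)
    else:
        z_elev_mun = np.zeros_like(mun_elev)
    amp = np.clip(1.0 + config.amplitude_elevation_slope * z_elev_mun, 0.2, None)
    rodent_years = config.rodent_years
    rows = []
    for i, mid in enumerate(municipalities["municipality_id"]):
        base = simulate_population_series(
            order=2,
            params=config.rodent_ar_params,
            noise_sd=config.rodent_noise_sd,
            length=len(rodent_years),
            rng=s_rodent,
        )
        scaled = base.mean() + amp[i] * (base - base.mean())
        rows.extend(
            (mid, int(yr), float(v)) for yr, v in zip(rodent_years, scaled)
        )
    rodent_truth = pd.DataFrame(rows, columns=["municipality_id", "year", "log_abundance"])

    # --- habitat patches: spruce everywhere, agriculture in southern lowlands
    spruce = pd.DataFrame(
        {
            "x_km": s_patches.uniform(0, w, config.n_spruce_patches),
            "y_km": s_patches.uniform(0, h, config.n_spruce_patches),
            "size": s_patches.lognormal(0.0, 0.6, config.n_spruce_patches),
            "class": "spruce",
        }
    )
    # southern bias: acceptance-rejection against an exponential northing decay
    ys = []
    while len(ys) < config.n_agri_patches:
        cand = s_patches.uniform(0, h, config.n_agri_patches)
        keep = s_patches.uniform(size=cand.size) < np.exp(-cand / (0.3 * h))
        ys.extend(cand[keep].tolist())
    agri = pd.DataFrame(
        {
            "x_km": s_patches.uniform(0, w, config.n_agri_patches),
            "y_km": np.array(ys[: config.n_agri_patches]),
            "size": s_patches.lognormal(0.0, 0.6, config.n_agri_patches),
            "class": "agriculture",
        }
    )
    patches = pd.concat([spruce, agri], ignore_index=True)

    spruce_density = patch_kernel_density(spruce, grid, bandwidth_km=5.0)
    agri_density = patch_kernel_density(agri, grid, bandwidth_km=5.0)

    # --- transect network and survey visits --------------------------------
    tx = s_transects.uniform(0, w, config.n_transects)
    ty = s_transects.uniform(0, h, config.n_transects)
    lengths = _truncated_normal(s_transects, 2.93, 0.51, 0.5, config.n_transects)
    tids = [f"T{i + 1:04d}" for i in range(config.n_transects)]
    # nearest municipality centroid == containing Voronoi cell
    d2 = (tx[:, None] - centroids[:, 0]) ** 2 + (ty[:, None] - centroids[:, 1]) ** 2
    mun_of_transect = municipalities["municipality_id"].to_numpy()[np.argmin(d2, axis=1)]

    trow, tcol = dem.cell_index(tx, ty, clamp=True)
    elev_t = dem.values[trow, tcol]
    spruce_t = spruce_density.values[trow, tcol]
    agri_t = agri_density.values[trow, tcol]

    rodent_wide = rodent_truth.pivot(
        index="municipality_id", columns="year", values="log_abundance"
    )
    records = []
    for year in config.year_range:
        surveyed = s_transects.uniform(size=config.n_transects) < config.survey_prob
        idx = np.flatnonzero(surveyed)
        if idx.size == 0:
            continue
        days = _truncated_normal(s_transects, 3.70, 1.65, 1.0, idx.size)
        # snow deepens with elevation, but weakly enough that the
        # collinearity screen (|r| < 0.6) passes as in the real survey design
        snow = np.maximum(
            20.0 + 0.02 * elev_t[idx] + s_transects.normal(0.0, 12.0, idx.size), 0.0
        )
        rodent_prev = rodent_wide.loc[mun_of_transect[idx], year - 1].to_numpy()
        records.append(
            pd.DataFrame(
                {
                    "transect_id": np.array(tids)[idx],
                    "municipality_id": mun_of_transect[idx],
                    "year": year,
                    "x_km": tx[idx],
                    "y_km": ty[idx],
                    "length_km": lengths[idx],
                    "days_since_snow": days,
                    "snow_cm": snow,
                    "elevation_m": elev_t[idx],
                    "spruce_density": spruce_t[idx],
                    "agri_density": agri_t[idx],
                    "rodent_log_abundance": rodent_prev,
                }
            )
        )
    transects = pd.concat(records, ignore_index=True)

    # standardized true covariates (the generator's design matrix)
    constants = {}
    for raw, name in [
        ("rodent_log_abundance", "rodent_index"),
        ("elevation_m", "elevation"),
        ("snow_cm", "snow"),
        ("spruce_density", "spruce_density"),
        ("agri_density", "agri_density"),
    ]:
        z, m, s = z_standardize(transects[raw].to_numpy())
        transects[f"z_{name}"] = z
        constants[name] = {"mean": m, "sd": s}
    transects["z_rodent_x_elevation"] = (
        transects["z_rodent_index"] * transects["z_elevation"]
    )

    world = SyntheticWorld(
        config=config,
        transects=transects,
        municipalities=municipalities,
        rodent_truth=rodent_truth,
        rodent_surveys=pd.DataFrame(),
        snap_traps=pd.DataFrame(),
        patches=patches,
        elevation=dem,
        truth={
            "true_delta": list(config.true_delta),
            "nb_dispersion": config.nb_dispersion,
            "year_effect_sd": config.year_effect_sd,
            "group_effect_sd": config.group_effect_sd,
            "rodent_ar_params": list(config.rodent_ar_params),
            "rodent_noise_sd": config.rodent_noise_sd,
            "amplitude_elevation_slope": config.amplitude_elevation_slope,
            "detection_slope": config.detection_slope,
            "standardization": constants,
            "seed": config.seed,
        },
    )

    counts, year_effects = simulate_marten_tracks(
        world,
        config.true_delta,
        config.nb_dispersion,
        config.year_effect_sd,
        rng=s_tracks,
    )
    world.transects["tracks"] = counts
    world.truth["year_effects"] = {int(y): float(v) for y, v in year_effects.items()}

    surveys, snap = simulate_rodent_surveys(
        world,
        config.n_lines_per_municipality,
        config.detection_slope,
        rng=s_surveys,
    )
    world.rodent_surveys = surveys
    world.snap_traps = snap
    return world


def simulate_marten_tracks(
    world: SyntheticWorld,
    true_delta,
    nb_dispersion: float,
    year_effect_sd: float,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, dict[int, float]]:
    """Negative-binomial track counts with log-effort offsets.

        log mu = log(length_km) + log(days) + delta0 + delta' z + v_year

    with v_year ~ N(0, year_effect_sd^2) and counts ~ NB(mu, theta), i.e.
    variance mu + mu^2/theta.  ``nb_dispersion = inf`` gives the Poisson
    limit.  Returns the counts (aligned with ``world.transects`` rows) and
    the drawn year effects.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    delta = np.asarray(true_delta, dtype=float)
    if len(delta) != 1 + len(COVARIATE_ORDER):
        raise ValueError(f"true_delta must have {1 + len(COVARIATE_ORDER)} entries")
    if not (nb_dispersion > 0):
        raise ValueError("nb_dispersion must be positive")
    df = world.transects
    zcols = [f"z_{c}" for c in COVARIATE_ORDER]
    missing = [c for c in zcols if c not in df.columns]
    if missing:
        raise ValueError(f"missing covariates: {missing}")

    years = np.sort(df["year"].unique())
    v = dict(zip(years.tolist(), rng.normal(0.0, year_effect_sd, size=len(years))))
    eta = (
        np.log(df["length_km"].to_numpy())
        + np.log(df["days_since_snow"].to_numpy())
        + delta[0]
        + df[zcols].to_numpy() @ delta[1:]
        + df["year"].map(v).to_numpy()
    )
    mu = np.exp(eta)
    if np.isinf(nb_dispersion):
        counts = rng.poisson(mu)
    else:
        p = nb_dispersion / (nb_dispersion + mu)
        counts = rng.negative_binomial(nb_dispersion, p)
    return counts.astype(int), v


def simulate_rodent_surveys(
    world: SyntheticWorld,
    n_lines_per_municipality: int,
    detection_slope: float,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Line-transect presence/absence surveys plus a snap-trap validation series.

    Each of the ``n_lines_per_municipality`` lines detects rodents with
    probability logistic(detection_slope * (x_mt - mean_m x_mt)) where x is
    the municipality's latent log abundance.  The snap-trap series (catches
    per 100 trap-days) is a noisy exponential transform of the latent
    abundance of the highest-elevation municipality, mimicking an
    independent density estimate from a mountain site.
    """
    if n_lines_per_municipality < 1:
        raise ValueError("need at least one line per municipality")
    if rng is None:
        rng = np.random.default_rng(seed)
    mun = world.municipalities.set_index("municipality_id")
    rows = []
    for mid, g in world.rodent_truth.groupby("municipality_id", sort=True):
        x = g["log_abundance"].to_numpy()
        p = 1.0 / (1.0 + np.exp(-detection_slope * (x - x.mean())))
        det = rng.binomial(n_lines_per_municipality, p)
        for year, d in zip(g["year"], det):
            rows.append(
                (
                    mid,
                    int(year),
                    n_lines_per_municipality,
                    int(d),
                    float(mun.loc[mid, "centroid_x_km"]),
                    float(mun.loc[mid, "centroid_y_km"]),
                )
            )
    surveys = pd.DataFrame(
        rows,
        columns=[
            "municipality_id",
            "year",
            "lines_total",
            "lines_with_detection",
            "centroid_x_km",
            "centroid_y_km",
        ],
    )

    trap_mid = world.municipalities.loc[
        world.municipalities["elevation_m"].idxmax(), "municipality_id"
    ]
    g = world.rodent_truth[world.rodent_truth["municipality_id"] == trap_mid]
    x = g["log_abundance"].to_numpy()
    noise = rng.normal(0.0, world.config.snap_trap_noise_sd, size=len(x))
    catches = 5.0 * np.exp(x - x.mean() + noise)
    snap = pd.DataFrame(
        {
            "municipality_id": trap_mid,
            "year": g["year"].to_numpy(),
            "catches_per_100_trapdays": catches,
        }
    )
    return surveys, snap


def simulate_abundance_dataset(
    n: int,
    true_delta=DEFAULT_TRUE_DELTA,
    nb_dispersion: float = 1.5,
    year_effect_sd: float = 0.2,
    years: tuple[int, int] = (2007, 2014),
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Model-ready negative-binomial count data with known coefficients.

    Generates standardized covariates directly (independent standard
    normals plus their interaction), survey-design effort offsets, year
    random effects and NB counts — the exact data-generating process the
    abundance GLMM assumes, for parameter-recovery validation.  Returns
    the frame and the generating truth.
    """
    rng = np.random.default_rng(seed)
    delta = np.asarray(true_delta, dtype=float)
    base = ("rodent_index", "elevation", "snow", "spruce_density", "agri_density")
    df = pd.DataFrame(rng.standard_normal((n, len(base))), columns=list(base))
    df["rodent_x_elevation"] = df["rodent_index"] * df["elevation"]
    df["length_km"] = _truncated_normal(rng, 2.93, 0.51, 0.5, n)
    df["days_since_snow"] = _truncated_normal(rng, 3.70, 1.65, 1.0, n)
    yr = np.arange(years[0], years[1] + 1)
    df["year"] = rng.choice(yr, size=n)
    v = dict(zip(yr.tolist(), rng.normal(0.0, year_effect_sd, len(yr))))
    eta = (
        np.log(df["length_km"])
        + np.log(df["days_since_snow"])
        + delta[0]
        + df[list(COVARIATE_ORDER)].to_numpy() @ delta[1:]
        + df["year"].map(v)
    )
    mu = np.exp(eta)
    df["tracks"] = rng.negative_binomial(nb_dispersion, nb_dispersion / (nb_dispersion + mu))
    truth = {
        "delta": delta.copy(),
        "nb_dispersion": nb_dispersion,
        "year_effects": v,
        "year_effect_sd": year_effect_sd,
    }
    return df, truth


# ---------------------------------------------------------------------------
# serialization

def write_world(world: SyntheticWorld, outdir) -> dict[str, Path]:
    """Write the world as plain-text artefacts (CSV/GeoJSON/ASC/YAML)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}

    cols = [
        "transect_id",
        "municipality_id",
        "year",
        "x_km",
        "y_km",
        "length_km",
        "days_since_snow",
        "tracks",
        "snow_cm",
    ]
    paths["transects"] = outdir / "transects.csv"
    world.transects[cols].to_csv(paths["transects"], index=False)

    features = []
    for _, row in world.municipalities.iterrows():
        features.append(
            {
                "type": "Feature",
                "properties": {
                    "municipality_id": row["municipality_id"],
                    "centroid_x_km": row["centroid_x_km"],
                    "centroid_y_km": row["centroid_y_km"],
                    "elevation_m": row["elevation_m"],
                },
                "geometry": mapping(row["polygon"]),
            }
        )
    paths["municipalities"] = outdir / "municipalities.geojson"
    paths["municipalities"].write_text(
        json.dumps({"type": "FeatureCollection", "features": features})
    )

    paths["rodent_surveys"] = outdir / "rodent_surveys.csv"
    world.rodent_surveys.to_csv(paths["rodent_surveys"], index=False)
    paths["snap_traps"] = outdir / "snap_traps.csv"
    world.snap_traps.to_csv(paths["snap_traps"], index=False)
    paths["patches"] = outdir / "patches.csv"
    world.patches.to_csv(paths["patches"], index=False)
    paths["elevation"] = outdir / "elevation.asc"
    world.elevation.to_ascii(paths["elevation"])

    truth = dict(world.truth)
    truth["config"] = {
        k: (list(v) if isinstance(v, tuple) else v) for k, v in asdict(world.config).items()
    }
    paths["truth"] = outdir / "truth.yaml"
    paths["truth"].write_text(yaml.safe_dump(truth, sort_keys=True))
    return paths
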