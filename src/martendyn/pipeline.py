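"""End-to-end orchestration of the population-dynamics analysis.

Stages, in the order they consume each other's outputs:

1. obtain data — either generate a synthetic world or ingest CSV/GeoJSON/
   ASCII-grid files;
2. abundance indices — per-visit effort-corrected track index, proximity
   clustering, group-mean annual series and growth rates;
3. PRCF — density-dependence/cyclicity diagnosis per gap-free series with
   more than ``min_steps`` observations, plus the majority-order summary;
4. rodent surface — municipality detection-proportion index, IDW raster
   per survey year, extraction at transect centroids (January tracks of
   year t are paired with the autumn rodent index of year t-1);
5. landscape covariates — home-range-grid mean elevation, spruce and
   agricultural kernel densities, z-standardization, collinearity screen;
6. GLMMs — Bayesian growth-rate and abundance models with 80% credible
   intervals and convergence diagnostics;
7. report — a single JSON mirroring the structure of the analysis output:
   PRCF majority statement, growth-model beta table, abundance-model delta
   table and the snap-trap validation r^2.

Every stage logs row counts; all randomness derives from ``RunConfig.seed``
so a rerun reproduces every number, posterior draws included.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import glmm, indices, landscape, prcf, rodent_surface
from .rodent_surface import GridSpec, Raster
from .synthetic_world import SimConfig, build_world, write_world

log = logging.getLogger("martendyn")


@dataclass
class RunConfig:
    """Everything a full pipeline run needs, with seeded reproducibility."""

    sim: SimConfig | None = None           # generate a world ...
    input_dir: str | Path | None = None    # ... or ingest files from here
    target_group_size: int = 10
    min_steps: int = 3
    max_lag: int = 5
    zero_policy: str | tuple = "half-min"
    idw_power: float = 2.0
    idw_neighbors: int = 12
    rodent_cell_dx_km: float = 1.9
    rodent_cell_dy_km: float = 3.0
    home_range_area_km2: float = 7.17
    bandwidth_km: float = 5.0
    chains: int = 4
    iterations: int = 6000
    warmup: int = 3000
    outdir: str | Path | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sim is None and self.input_dir is None:
            self.sim = SimConfig(seed=self.seed)


def _load_inputs(config: RunConfig):
    """Load the five input artefacts, from disk or by simulation."""
    if config.input_dir is not None:
        d = Path(config.input_dir)
        issues = validate_inputs(
            {
                "transects": d / "transects.csv",
                "rodent_surveys": d / "rodent_surveys.csv",
                "elevation": d / "elevation.asc",
                "patches": d / "patches.csv",
            }
        )
        fatal = [i for i in issues if i["fatal"]]
        if fatal:
            raise ValueError(f"input validation failed: {fatal}")
        transects = pd.read_csv(d / "transects.csv")
        surveys = pd.read_csv(d / "rodent_surveys.csv")
        dem = Raster.from_ascii(d / "elevation.asc")
        patches = pd.read_csv(d / "patches.csv")
        snap_path = d / "snap_traps.csv"
        snap = pd.read_csv(snap_path) if snap_path.exists() else None
        return transects, surveys, dem, patches, snap, None
    world = build_world(config.sim)
    return (
        world.transects,
        world.rodent_surveys,
        world.elevation,
        world.patches,
        world.snap_traps,
        world,
    )


def run_all(config: RunConfig) -> dict:
    """Execute the full analysis and return (and optionally write) the report."""
    rng_seed = int(config.seed)
    outdir = Path(config.outdir) if config.outdir is not None else None
    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)

    def stage(name):
        log.info("stage: %s", name)

    stage("inputs")
    transects, surveys, dem, patches, snap, world = _load_inputs(config)
    log.info("transect-year records: %d; rodent survey rows: %d", len(transects), len(surveys))
    if outdir is not None and world is not None:
        write_world(world, outdir / "world")

    # ------------------------------------------------------------------ indices
    stage("indices")
    assignment = indices.cluster_transects(transects, config.target_group_size, seed=rng_seed)
    series = indices.group_mean_series(transects, assignment)
    eligible = indices.eligible_series(series, config.min_steps)
    eligible = [indices.growth_rates(s, config.zero_policy) for s in eligible]
    log.info("groups: %d; eligible gap-free runs (> %d steps): %d",
             len(series), config.min_steps, len(eligible))

    # --------------------------------------------------------------------- prcf
    stage("prcf")
    prcf_results = [
        prcf.prcf(s.mean_index, max_lag=config.max_lag, zero_policy=config.zero_policy,
                  series_id=s.group_id)
        for s in eligible
    ]
    feedback = prcf.classify_feedback(prcf_results)

    # ----------------------------------------------------------- rodent surface
    stage("rodent_surface")
    surveys_ix = rodent_surface.municipality_index(surveys)
    grid = GridSpec.from_extent(
        dem.x_min, dem.y_min, dem.x_max, dem.y_max,
        config.rodent_cell_dx_km, config.rodent_cell_dy_km,
    )
    rasters: dict[int, Raster] = {}
    for year, g in surveys_ix.groupby("year"):
        pts = g[["centroid_x_km", "centroid_y_km", "rodent_index"]].to_numpy()
        rasters[int(year)] = rodent_surface.idw_interpolate(
            pts, grid, power=config.idw_power, n_neighbors=config.idw_neighbors
        )
    if outdir is not None:
        (outdir / "rodent_rasters").mkdir(exist_ok=True)
        for year, r in rasters.items():
            r.to_ascii(outdir / "rodent_rasters" / f"rodent_index_{year}.asc")

    # January tracks of year t pair with the previous autumn's rodent surface
    transects = transects.copy()
    transects["rodent_index"] = np.nan
    for year in sorted(transects["year"].unique()):
        if year - 1 not in rasters:
            continue
        m = transects["year"] == year
        transects.loc[m, "rodent_index"] = rodent_surface.extract_at(
            rasters[year - 1], transects.loc[m, "x_km"], transects.loc[m, "y_km"]
        )

    # ------------------------------------------------------------------ landscape
    stage("landscape")
    transects["elevation"] = landscape.mean_elevation_at(
        dem, transects["x_km"], transects["y_km"], config.home_range_area_km2
    )
    dens_grid = GridSpec.from_extent(
        dem.x_min, dem.y_min, dem.x_max, dem.y_max, dem.cell_dx_km, dem.cell_dy_km
    )
    density_rasters = {}
    for cls in ("spruce", "agriculture"):
        sub = patches[patches["class"] == cls]
        density_rasters[cls] = landscape.patch_kernel_density(
            sub, dens_grid, config.bandwidth_km
        )
    transects["spruce_density_cov"] = rodent_surface.extract_at(
        density_rasters["spruce"], transects["x_km"], transects["y_km"]
    )
    transects["agri_density_cov"] = rodent_surface.extract_at(
        density_rasters["agriculture"], transects["x_km"], transects["y_km"]
    )
    transects["snow_cov"] = transects["snow_cm"]

    raw_cols = {
        "rodent_index": "rodent_index",
        "elevation": "elevation",
        "snow": "snow_cov",
        "spruce_density": "spruce_density_cov",
        "agri_density": "agri_density_cov",
    }
    model_rows = transects.dropna(subset=list(raw_cols.values())).copy()
    screen_table = model_rows[[c for c in raw_cols.values()]].rename(
        columns={v: k for k, v in raw_cols.items()}
    )
    corr, flagged = landscape.collinearity_screen(screen_table)
    log.info("abundance-model rows: %d; collinearity flags: %d", len(model_rows), len(flagged))

    # --------------------------------------------------------------- GLMM data
    stage("glmm_data")
    constants = {}
    for name, col in raw_cols.items():
        z, m, s = landscape.z_standardize(model_rows[col].to_numpy())
        model_rows[f"z_{name}"] = z
        constants[name] = {"mean": m, "sd": s}
    model_rows["z_rodent_x_elevation"] = (
        model_rows["z_rodent_index"] * model_rows["z_elevation"]
    )

    abundance_data = pd.DataFrame(
        {
            "tracks": model_rows["tracks"].to_numpy(),
            "year": model_rows["year"].to_numpy(),
            "length_km": model_rows["length_km"].to_numpy(),
            "days_since_snow": model_rows["days_since_snow"].to_numpy(),
            **{c: model_rows[f"z_{c}"].to_numpy() for c in glmm.ABUNDANCE_COVARIATES},
        }
    )

    # growth model: response is the growth of the group-mean index; covariates
    # are group-year means of member transects' raw covariates, standardized
    # over the growth-model rows
    growth_rows = []
    gm = model_rows.copy()
    gm["group_id"] = gm["transect_id"].map(assignment)
    group_year_cov = gm.groupby(["group_id", "year"])[
        ["rodent_index", "elevation", "snow_cov"]
    ].mean()
    for s in eligible:
        for y, r in zip(s.years, s.growth_rate):
            if not np.isfinite(r):
                continue
            base_gid = s.group_id.split(".run")[0]
            key = (base_gid, int(y))
            if key not in group_year_cov.index:
                continue
            cov = group_year_cov.loc[key]
            growth_rows.append(
                {
                    "group_id": base_gid,
                    "year": int(y),
                    "growth_rate": float(r),
                    "rodent_raw": cov["rodent_index"],
                    "elevation_raw": cov["elevation"],
                    "snow_raw": cov["snow_cov"],
                }
            )
    growth_data = pd.DataFrame(growth_rows)
    if len(growth_data) >= 10:
        for name, col in [
            ("rodent_index", "rodent_raw"),
            ("elevation", "elevation_raw"),
            ("snow", "snow_raw"),
        ]:
            z, _, _ = landscape.z_standardize(growth_data[col].to_numpy())
            growth_data[name] = z
        growth_data["rodent_x_elevation"] = (
            growth_data["rodent_index"] * growth_data["elevation"]
        )
    log.info("growth-model rows: %d", len(growth_data))

    # -------------------------------------------------------------------- fits
    stage("glmm_fit")
    abundance_fit = glmm.fit(
        glmm.AbundanceModelSpec(),
        abundance_data,
        chains=config.chains,
        iterations=config.iterations,
        warmup=config.warmup,
        seed=rng_seed + 1,
    )
    growth_fit = None
    if len(growth_data) >= 10 and growth_data["group_id"].nunique() >= 2:
        growth_fit = glmm.fit(
            glmm.GrowthModelSpec(),
            growth_data,
            chains=config.chains,
            iterations=config.iterations,
            warmup=config.warmup,
            seed=rng_seed + 2,
        )

    # -------------------------------------------------------------- validation
    stage("validation")
    validation = None
    if snap is not None and len(snap) >= 3:
        trap_mid = snap["municipality_id"].iloc[0] if "municipality_id" in snap else None
        ix = surveys_ix
        if trap_mid is not None:
            ix = surveys_ix[surveys_ix["municipality_id"] == trap_mid]
        merged = pd.merge(
            ix[["year", "rodent_index"]],
            snap[["year", "catches_per_100_trapdays"]],
            on="year",
        )
        if len(merged) >= 3:
            r, r2, p = rodent_surface.validate_against_traps(
                merged["rodent_index"], merged["catches_per_100_trapdays"]
            )
            validation = {
                "municipality_id": trap_mid,
                "n_years": int(len(merged)),
                "r": r,
                "r_squared": r2,
                "p_value": p,
            }

    # ------------------------------------------------------------------ report
    stage("report")

    def fixed_table(post):
        if post is None:
            return None
        summ = post.summary()
        fe = [n for n in post.names if n.startswith(("beta_", "delta_"))]
        tbl = summ.loc[fe]
        return {
            name: {
                "mean": float(row["mean"]),
                "cri_lower": float(row.iloc[1]),
                "cri_upper": float(row.iloc[2]),
                "excludes_zero": bool(row["excludes_zero"]),
                "rhat": float(row["rhat"]),
            }
            for name, row in tbl.iterrows()
        }

    report = {
        "seed": rng_seed,
        "n_transect_year_records": int(len(transects)),
        "prcf": {
            "n_series": feedback["n_series"],
            "n_argmin_lag1": feedback["n_argmin_lag1"],
            "argmin_lag_counts": feedback["argmin_lag_counts"],
            "order_counts": feedback["order_counts"],
        },
        "collinearity": {
            "max_abs_r": float(np.abs(corr.to_numpy() - np.eye(len(corr))).max()),
            "flagged_pairs": [(a, b, r) for a, b, r in flagged],
        },
        "growth_model": fixed_table(growth_fit),
        "abundance_model": fixed_table(abundance_fit),
        "abundance_converged": bool(abundance_fit.converged),
        "growth_converged": bool(growth_fit.converged) if growth_fit is not None else None,
        "validation": validation,
    }
    if world is not None:
        report["truth"] = {
            "true_delta": world.truth["true_delta"],
            "nb_dispersion": world.truth["nb_dispersion"],
        }

    if outdir is not None:
        series_df = indices.series_to_frame(eligible)
        series_df.to_csv(outdir / "group_series.csv", index=False)
        pd.DataFrame(
            sorted(assignment.items()), columns=["transect_id", "group_id"]
        ).to_csv(outdir / "group_assignment.csv", index=False)
        feedback["per_series"].to_csv(outdir / "prcf_results.csv", index=False)
        abundance_fit.summary().to_csv(outdir / "abundance_posterior_summary.csv")
        if growth_fit is not None:
            growth_fit.summary().to_csv(outdir / "growth_posterior_summary.csv")
        (outdir / "report.json").write_text(json.dumps(report, indent=2, default=float))
        manifest = {
            "seed": rng_seed,
            "stages": [
                "inputs", "indices", "prcf", "rodent_surface",
                "landscape", "glmm_fit", "validation", "report",
            ],
            "outputs": sorted(str(p.relative_to(outdir)) for p in outdir.rglob("*") if p.is_file()),
        }
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))

    # keep the heavyweight objects accessible to callers without bloating JSON
    report["_objects"] = {
        "abundance_fit": abundance_fit,
        "growth_fit": growth_fit,
        "eligible_series": eligible,
        "prcf_results": prcf_results,
        "abundance_data": abundance_data,
        "growth_data": growth_data,
        "standardization": constants,
    }
    return report


def validate_inputs(paths: dict) -> list[dict]:
    """Schema checks for the pipeline's file inputs.

    Returns a machine-readable issue list; issues with ``fatal=True`` should
    abort the run.  Recognised keys: ``transects``, ``rodent_surveys``,
    ``elevation``, ``patches``.
    """
    issues: list[dict] = []

    def issue(file, message, fatal=True, row=None):
        issues.append({"file": str(file), "message": message, "fatal": fatal, "row": row})

    p = paths.get("transects")
    if p is not None:
        try:
            df = pd.read_csv(p)
        except Exception as e:  # unreadable file is fatal
            issue(p, f"unreadable: {e}")
            df = None
        if df is not None:
            for col in indices.REQUIRED_TRANSECT_COLUMNS:
                if col not in df.columns:
                    issue(p, f"missing required column {col!r}")
            if "days_since_snow" in df.columns:
                bad = df.index[df["days_since_snow"] <= 0]
                if len(bad):
                    issue(p, "days_since_snow must be >= 1", row=int(bad[0]))
            if "length_km" in df.columns:
                bad = df.index[df["length_km"] <= 0]
                if len(bad):
                    issue(p, "length_km must be positive", row=int(bad[0]))
            if "tracks" in df.columns:
                bad = df.index[df["tracks"] < 0]
                if len(bad):
                    issue(p, "tracks must be non-negative", row=int(bad[0]))

    p = paths.get("rodent_surveys")
    if p is not None:
        try:
            df = pd.read_csv(p)
        except Exception as e:
            issue(p, f"unreadable: {e}")
            df = None
        if df is not None:
            for col in (
                "municipality_id", "year", "lines_total", "lines_with_detection",
                "centroid_x_km", "centroid_y_km",
            ):
                if col not in df.columns:
                    issue(p, f"missing required column {col!r}")
            if {"lines_total", "lines_with_detection"} <= set(df.columns):
                bad = df.index[
                    (df["lines_total"] < 1)
                    | (df["lines_with_detection"] < 0)
                    | (df["lines_with_detection"] > df["lines_total"])
                ]
                if len(bad):
                    issue(p, "detection counts outside [0, lines_total]", row=int(bad[0]))

    p = paths.get("elevation")
    if p is not None:
        try:
            Raster.from_ascii(p)
        except Exception as e:
            issue(p, f"unreadable ASCII grid: {e}")

    p = paths.get("patches")
    if p is not None:
        try:
            df = pd.read_csv(p)
        except Exception as e:
            issue(p, f"unreadable: {e}")
            df = None
        if df is not None:
            for col in ("x_km", "y_km", "size", "class"):
                if col not in df.columns:
                    issue(p, f"missing required column {col!r}")
            if "size" in df.columns and (df["size"] <= 0).any():
                issue(p, "patch sizes must be positive",
                      row=int(df.index[df["size"] <= 0][0]))
    return issues
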