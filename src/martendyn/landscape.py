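"""Landscape covariates: elevation, habitat kernel densities, standardization.

Elevation is averaged over a home-range-sized square grid (cell area 7.17
km^2, the average pine marten home range) laid over the digital elevation
model, and each transect takes the mean of its containing cell.  Mature
spruce forest and agricultural land enter as planar kernel densities of
patch centres weighted by patch size.  All continuous covariates are
z-transformed before modelling and screened for pairwise collinearity
(|Pearson r| >= 0.6 flags a pair).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .rodent_surface import GridSpec, Raster

HOME_RANGE_AREA_KM2 = 7.17
COLLINEARITY_THRESHOLD = 0.6


def mean_elevation_at(
    dem: Raster, x, y, cell_area_km2: float = HOME_RANGE_AREA_KM2
) -> np.ndarray:
    """Mean elevation of the home-range grid cell containing each point.

    A square grid of cell side sqrt(cell_area_km2) is anchored at the DEM's
    south-west corner; each grid cell's value is the mean of the DEM pixels
    whose centres fall inside it, and each point takes its containing
    cell's mean.
    """
    x = np.atleast_1d(np.asarray(x, dtype=float))
    y = np.atleast_1d(np.asarray(y, dtype=float))
    if (
        (x < dem.x_min).any()
        or (x > dem.x_max).any()
        or (y < dem.y_min).any()
        or (y > dem.y_max).any()
    ):
        raise ValueError("point outside DEM extent")
    side = float(np.sqrt(cell_area_km2))

    px, py = dem.cell_centers()
    vals = dem.values.ravel()
    ok = np.isfinite(vals)
    col = np.floor((px.ravel() - dem.x_min) / side).astype(int)
    row = np.floor((py.ravel() - dem.y_min) / side).astype(int)
    n_cols = int(np.ceil((dem.x_max - dem.x_min) / side))
    n_rows = int(np.ceil((dem.y_max - dem.y_min) / side))
    flat = row * n_cols + col
    sums = np.bincount(flat[ok], weights=vals[ok], minlength=n_rows * n_cols)
    counts = np.bincount(flat[ok], minlength=n_rows * n_cols)
    with np.errstate(invalid="ignore"):
        cell_mean = sums / counts

    pcol = np.clip(np.floor((x - dem.x_min) / side).astype(int), 0, n_cols - 1)
    prow = np.clip(np.floor((y - dem.y_min) / side).astype(int), 0, n_rows - 1)
    out = cell_mean[prow * n_cols + pcol]
    empty = ~np.isfinite(out)
    if empty.any():
        # a sliver cell at the region edge can be narrower than one DEM
        # pixel and so contain no pixel centres; fall back to the DEM pixel
        # under the point itself
        drow, dcol = dem.cell_index(x[empty], y[empty], clamp=True)
        out[empty] = dem.values[drow, dcol]
    if not np.isfinite(out).all():
        raise ValueError("no DEM data under a point")
    return out


def patch_kernel_density(
    patches: pd.DataFrame, grid: GridSpec, bandwidth_km: float = 5.0
) -> Raster:
    """Size-weighted planar Gaussian kernel density of habitat patches.

    density(u) = sum_i size_i * exp(-|u - c_i|^2 / (2 h^2)) / (2 pi h^2),
    so the surface integrates (over the plane) to the total patch size.
    ``patches`` needs columns ``x_km, y_km, size``.
    """
    if bandwidth_km <= 0:
        raise ValueError("bandwidth must be positive")
    if len(patches) == 0:
        raise ValueError("no patches")
    if (patches["size"] <= 0).any():
        raise ValueError("patch sizes must be positive")
    raster = grid.empty()
    X, Y = raster.cell_centers()
    gx = X.ravel()
    gy = Y.ravel()
    h2 = bandwidth_km**2
    norm = 1.0 / (2.0 * np.pi * h2)
    out = np.zeros(gx.size)
    cx = patches["x_km"].to_numpy()
    cy = patches["y_km"].to_numpy()
    sz = patches["size"].to_numpy()
    # chunk over patches to bound the (cells x patches) distance matrix
    step = max(1, int(4e6 // max(gx.size, 1)))
    for i in range(0, len(cx), step):
        d2 = (gx[:, None] - cx[i : i + step]) ** 2 + (gy[:, None] - cy[i : i + step]) ** 2
        out += (sz[i : i + step] * np.exp(-d2 / (2.0 * h2))).sum(axis=1)
    raster.values = (norm * out).reshape(raster.n_rows, raster.n_cols)
    return raster


def z_standardize(values) -> tuple[np.ndarray, float, float]:
    """z-transform: subtract the mean, divide by the sample SD (ddof = 1).

    Returns ``(z, mean, sd)`` so the transform can be inverted or applied
    to new data with the fitted constants.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need at least 2 values to standardize")
    mean = float(np.mean(v))
    sd = float(np.std(v, ddof=1))
    if sd == 0:
        raise ValueError("zero variance: cannot standardize a constant")
    return (v - mean) / sd, mean, sd


def collinearity_screen(table: pd.DataFrame, threshold: float = COLLINEARITY_THRESHOLD):
    """Pairwise Pearson correlations among covariate columns, with flags.

    Returns ``(corr_matrix, flagged_pairs)`` where flagged pairs have
    |r| >= threshold.
    """
    if len(table) < 3:
        raise ValueError("need at least 3 rows for a correlation screen")
    corr = table.corr(method="pearson")
    cols = list(corr.columns)
    flagged = [
        (cols[i], cols[j], float(corr.iloc[i, j]))
        for i in range(len(cols))
        for j in range(i + 1, len(cols))
        if abs(corr.iloc[i, j]) >= threshold
    ]
    return corr, flagged
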