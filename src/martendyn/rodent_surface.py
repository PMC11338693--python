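"""Microtine rodent abundance index and its spatial interpolation.

Municipality-level rodent monitoring records, for each August survey, how
many line transects were walked and on how many of those live microtine
rodents (voles and lemmings) were seen.  The proportion of lines with a
detection is a conservative index of rodent abundance.  Because rodent lines
and marten snow transects do not overlap spatially, the index is interpolated
from municipality centroids across the whole region by inverse distance
weighting (IDW, power 2) onto a raster, and the raster is then sampled at
each snow-transect centroid.  An independent snap-trap series (catches per
100 trap-days) from one municipality is used to validate the index.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial import cKDTree

NODATA = -9999.0


@dataclass
class Raster:
    """Planar-km raster, row-major from the north-west corner.

    ``origin_x_km, origin_y_km`` is the top-left (north-west) corner of the
    grid; row 0 is the northernmost row.  Cells are half-open intervals
    ``[lo, hi)`` in x and ``(lo, hi]`` in y so every point maps to exactly
    one cell.
    """

    origin_x_km: float
    origin_y_km: float
    cell_dx_km: float
    cell_dy_km: float
    n_cols: int
    n_rows: int
    values: np.ndarray = field(repr=False)
    nodata: float = NODATA

    def __post_init__(self) -> None:
        if self.cell_dx_km <= 0 or self.cell_dy_km <= 0:
            raise ValueError("cell sizes must be positive")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.n_rows, self.n_cols):
            raise ValueError(
                f"values shape {self.values.shape} != ({self.n_rows}, {self.n_cols})"
            )

    # -- geometry ---------------------------------------------------------
    @property
    def x_min(self) -> float:
        return self.origin_x_km

    @property
    def x_max(self) -> float:
        return self.origin_x_km + self.n_cols * self.cell_dx_km

    @property
    def y_max(self) -> float:
        return self.origin_y_km

    @property
    def y_min(self) -> float:
        return self.origin_y_km - self.n_rows * self.cell_dy_km

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (X, Y) arrays of cell-centre coordinates, shape (rows, cols)."""
        xs = self.origin_x_km + (np.arange(self.n_cols) + 0.5) * self.cell_dx_km
        ys = self.origin_y_km - (np.arange(self.n_rows) + 0.5) * self.cell_dy_km
        return np.meshgrid(xs, ys)

    def cell_index(self, x, y, clamp: bool = False):
        """Map coordinates to (row, col); half-open convention [lo, hi)."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        col = np.floor((x - self.origin_x_km) / self.cell_dx_km).astype(int)
        row = np.floor((self.origin_y_km - y) / self.cell_dy_km).astype(int)
        # a point exactly on the top/left boundary belongs to row/col 0
        if clamp:
            col = np.clip(col, 0, self.n_cols - 1)
            row = np.clip(row, 0, self.n_rows - 1)
        return row, col

    # -- ESRI ASCII I/O ---------------------------------------------------
    def to_ascii(self, path) -> None:
        path = Path(path)
        if self.cell_dx_km == self.cell_dy_km:
            size = f"cellsize {self.cell_dx_km}\n"
        else:
            # rectangular cells via the GDAL AAIGrid dx/dy header extension
            size = f"dx {self.cell_dx_km}\ndy {self.cell_dy_km}\n"
        header = (
            f"ncols {self.n_cols}\n"
            f"nrows {self.n_rows}\n"
            f"xllcorner {self.x_min}\n"
            f"yllcorner {self.y_min}\n"
            + size
            + f"NODATA_value {self.nodata}\n"
        )
        vals = np.where(np.isfinite(self.values), self.values, self.nodata)
        with path.open("w") as fh:
            fh.write(header)
            np.savetxt(fh, vals, fmt="%.8g")

    @classmethod
    def from_ascii(cls, path) -> "Raster":
        path = Path(path)
        hdr: dict[str, float] = {}
        with path.open() as fh:
            pos = fh.tell()
            line = fh.readline()
            while line and line.split()[0].lower() in (
                "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "dx", "dy",
                "nodata_value",
            ):
                key, val = line.split()
                hdr[key.lower()] = float(val)
                pos = fh.tell()
                line = fh.readline()
            fh.seek(pos)
            values = np.loadtxt(fh)
        n_cols = int(hdr["ncols"])
        n_rows = int(hdr["nrows"])
        dx = hdr.get("dx", hdr.get("cellsize"))
        dy = hdr.get("dy", hdr.get("cellsize"))
        values = values.reshape(n_rows, n_cols)
        nodata = hdr.get("nodata_value", NODATA)
        values = np.where(values == nodata, np.nan, values)
        return cls(
            origin_x_km=hdr["xllcorner"],
            origin_y_km=hdr["yllcorner"] + n_rows * dy,
            cell_dx_km=dx,
            cell_dy_km=dy,
            n_cols=n_cols,
            n_rows=n_rows,
            values=values,
            nodata=nodata,
        )


@dataclass(frozen=True)
class GridSpec:
    """Extent and resolution for building a new raster (north-west origin)."""

    origin_x_km: float
    origin_y_km: float
    cell_dx_km: float
    cell_dy_km: float
    n_cols: int
    n_rows: int

    @classmethod
    def from_extent(cls, x_min, y_min, x_max, y_max, cell_dx_km, cell_dy_km):
        n_cols = int(np.ceil((x_max - x_min) / cell_dx_km))
        n_rows = int(np.ceil((y_max - y_min) / cell_dy_km))
        return cls(x_min, y_min + n_rows * cell_dy_km, cell_dx_km, cell_dy_km, n_cols, n_rows)

    def empty(self) -> Raster:
        return Raster(
            self.origin_x_km,
            self.origin_y_km,
            self.cell_dx_km,
            self.cell_dy_km,
            self.n_cols,
            self.n_rows,
            np.full((self.n_rows, self.n_cols), np.nan),
        )


def municipality_index(surveys: pd.DataFrame) -> pd.DataFrame:
    """Proportion of line transects with a rodent detection per municipality-year.

    Parameters
    ----------
    surveys
        Columns ``municipality_id, year, lines_total, lines_with_detection``
        (extra columns such as centroids are carried through).

    Returns
    -------
    DataFrame with an added ``rodent_index`` column in [0, 1].
    """
    out = surveys.copy()
    if (out["lines_total"] <= 0).any():
        bad = out.loc[out["lines_total"] <= 0].iloc[0]
        raise ValueError(
            f"lines_total must be >= 1 (municipality {bad['municipality_id']}, year {bad['year']})"
        )
    if ((out["lines_with_detection"] < 0) | (out["lines_with_detection"] > out["lines_total"])).any():
        raise ValueError("lines_with_detection must lie in [0, lines_total]")
    out["rodent_index"] = out["lines_with_detection"] / out["lines_total"]
    return out


def idw_interpolate(
    points,
    grid: GridSpec,
    power: float = 2.0,
    n_neighbors: int = 12,
) -> Raster:
    """Inverse-distance-weighted interpolation of point values onto a raster.

    ``points`` is an (n, 3) array-like of (x_km, y_km, value).  Each cell
    takes the weighted mean of its ``n_neighbors`` nearest points with
    weights d^-power; a cell whose centre lies within 1e-9 km of a data
    point takes that point's value exactly (IDW is an exact interpolator).
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[0] == 0 or pts.shape[1] != 3:
        raise ValueError("points must be a non-empty (n, 3) array of (x, y, value)")
    if power <= 0:
        raise ValueError("power must be positive")
    k = int(min(n_neighbors, pts.shape[0]))

    raster = grid.empty()
    X, Y = raster.cell_centers()
    tree = cKDTree(pts[:, :2])
    dist, idx = tree.query(np.column_stack([X.ravel(), Y.ravel()]), k=k)
    dist = np.atleast_2d(dist.reshape(-1, k))
    idx = np.atleast_2d(idx.reshape(-1, k))
    vals = pts[:, 2][idx]

    exact = dist[:, 0] < 1e-9
    with np.errstate(divide="ignore", invalid="ignore"):
        w = dist ** (-power)
        est = np.einsum("ij,ij->i", w, vals) / w.sum(axis=1)
    est[exact] = vals[exact, 0]
    raster.values = est.reshape(raster.n_rows, raster.n_cols)
    return raster


def extract_at(raster: Raster, x, y) -> np.ndarray:
    """Sample the raster at point locations (value of the containing cell).

    Points outside the raster extent are snapped to the nearest cell with a
    warning; no resampling or smoothing is applied.
    """
    x = np.atleast_1d(np.asarray(x, dtype=float))
    y = np.atleast_1d(np.asarray(y, dtype=float))
    if not np.isfinite(raster.values).any():
        raise ValueError("raster contains no data")
    row, col = raster.cell_index(x, y)
    outside = (row < 0) | (row >= raster.n_rows) | (col < 0) | (col >= raster.n_cols)
    if outside.any():
        warnings.warn(
            f"{int(outside.sum())} point(s) outside raster extent; snapped to nearest cell",
            stacklevel=2,
        )
        row = np.clip(row, 0, raster.n_rows - 1)
        col = np.clip(col, 0, raster.n_cols - 1)
    return raster.values[row, col]


def validate_against_traps(index_series, trap_series) -> tuple[float, float, float]:
    """Pearson correlation between the rodent index and an independent snap-trap series.

    Returns ``(r, r_squared, p_value)`` with the two-sided p-value from the
    t-distribution with n - 2 degrees of freedom.  Series must be paired by
    year (same length, same order) with n >= 3.
    """
    a = np.asarray(index_series, dtype=float)
    b = np.asarray(trap_series, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("series must be paired 1-d arrays of equal length")
    if a.size < 3:
        raise ValueError("need at least 3 paired years")
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("zero variance in one of the series")
    res = stats.pearsonr(a, b)
    return float(res.statistic), float(res.statistic**2), float(res.pvalue)
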