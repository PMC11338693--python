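"""Snow-track abundance indices, transect grouping and population growth rates.

The effort-corrected abundance index for one transect visit is

    index = tracks / (transect length [km] * days since last snowfall)

in tracks km^-1 day^-1.  Transects are grouped by spatial proximity
(k-means on their centroids, about ten transects per group) so that the
group-mean index forms annual time series N_t long enough for time-series
diagnostics; the realized per-capita growth rate is R_t = ln(N_t / N_{t-1}).
Years in which no member transect was surveyed split a group's series into
consecutive runs, and only runs with more than ``min_steps`` observations
are retained for the feedback analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

REQUIRED_TRANSECT_COLUMNS = (
    "transect_id",
    "year",
    "x_km",
    "y_km",
    "length_km",
    "days_since_snow",
    "tracks",
)


@dataclass
class GroupSeries:
    """Annual mean abundance-index series for one transect group (one run)."""

    group_id: str
    member_transect_ids: frozenset
    years: np.ndarray
    mean_index: np.ndarray
    growth_rate: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years, dtype=int)
        self.mean_index = np.asarray(self.mean_index, dtype=float)
        if np.any(np.diff(self.years) <= 0):
            raise ValueError(f"group {self.group_id}: years must be strictly increasing")
        if (self.mean_index < 0).any():
            raise ValueError(f"group {self.group_id}: mean_index must be non-negative")

    def __len__(self) -> int:
        return len(self.years)

    def runs(self) -> list["GroupSeries"]:
        """Split at year gaps into consecutive runs (growth rates dropped)."""
        breaks = np.flatnonzero(np.diff(self.years) > 1) + 1
        chunks = np.split(np.arange(len(self.years)), breaks)
        out = []
        for j, ix in enumerate(chunks):
            gid = self.group_id if len(chunks) == 1 else f"{self.group_id}.run{j + 1}"
            out.append(
                GroupSeries(gid, self.member_transect_ids, self.years[ix], self.mean_index[ix])
            )
        return out


def abundance_index(tracks, length_km, days_since_snow):
    """Effort-corrected track index: tracks / (length_km * days_since_snow).

    All arguments broadcast; raises on non-positive effort terms or
    negative counts.
    """
    tracks = np.asarray(tracks, dtype=float)
    length_km = np.asarray(length_km, dtype=float)
    days = np.asarray(days_since_snow, dtype=float)
    if np.any(length_km <= 0):
        raise ValueError("length_km must be strictly positive")
    if np.any(days <= 0):
        raise ValueError("days_since_snow must be strictly positive")
    if np.any(tracks < 0):
        raise ValueError("tracks must be non-negative")
    out = tracks / (length_km * days)
    return float(out) if out.ndim == 0 else out


def cluster_transects(
    records: pd.DataFrame, target_group_size: int = 10, seed: int = 0
) -> dict[str, str]:
    """Group transects by proximity into clusters of about ``target_group_size``.

    k-means on the unique transect centroids with k = round(n / target);
    the assignment is a property of the transect, not the visit, so it is
    identical across years.  Returns a transect_id -> group_id map.
    """
    unique = (
        records[["transect_id", "x_km", "y_km"]]
        .drop_duplicates("transect_id")
        .sort_values("transect_id", kind="stable")
        .reset_index(drop=True)
    )
    n = len(unique)
    if n == 0:
        raise ValueError("no transects to cluster")
    k = int(round(n / target_group_size))
    if k < 1 or n < target_group_size:
        warnings.warn(
            f"only {n} transects for target group size {target_group_size}; using a single group",
            stacklevel=2,
        )
        k = 1
    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    labels = km.fit_predict(unique[["x_km", "y_km"]].to_numpy())
    width = max(2, len(str(k)))
    return {
        tid: f"G{lab + 1:0{width}d}" for tid, lab in zip(unique["transect_id"], labels)
    }


def group_mean_series(records: pd.DataFrame, assignment: dict[str, str]) -> list[GroupSeries]:
    """Per-group annual mean of member transects' abundance indices.

    Years in which no member transect was surveyed are simply absent from
    the series (a gap); downstream callers split on gaps via
    :meth:`GroupSeries.runs`.
    """
    missing = set(records["transect_id"]) - set(assignment)
    if missing:
        raise ValueError(f"assignment does not cover transects: {sorted(missing)[:5]} ...")
    df = records.copy()
    df["index"] = abundance_index(df["tracks"], df["length_km"], df["days_since_snow"])
    df["group_id"] = df["transect_id"].map(assignment)
    out = []
    for gid, g in df.groupby("group_id", sort=True):
        series = g.groupby("year")["index"].mean().sort_index()
        out.append(
            GroupSeries(
                group_id=str(gid),
                member_transect_ids=frozenset(g["transect_id"]),
                years=series.index.to_numpy(),
                mean_index=series.to_numpy(),
            )
        )
    return out


def apply_zero_policy(values: np.ndarray, zero_policy="half-min") -> np.ndarray:
    """Make a non-negative series strictly positive before taking logs.

    Policies: ``"half-min"`` (default) adds half the smallest positive value
    to every observation; ``("constant", c)`` adds the fixed c; ``"drop"``
    leaves zeros in place for the caller to mask out; ``"none"`` requires
    an already-positive series.
    """
    values = np.asarray(values, dtype=float)
    if (values < 0).any():
        raise ValueError("series values must be non-negative")
    if isinstance(zero_policy, tuple) and zero_policy[0] == "constant":
        return values + float(zero_policy[1])
    if zero_policy == "none":
        if (values == 0).any():
            raise ValueError("series contains zeros; choose a zero policy")
        return values
    if zero_policy == "drop":
        return values
    if zero_policy == "half-min":
        positive = values[values > 0]
        if positive.size == 0:
            raise ValueError("all-zero series: cannot form a log index")
        if (values == 0).any():
            return values + positive.min() / 2.0
        return values
    raise ValueError(f"unknown zero policy {zero_policy!r}")


def growth_rates(series: GroupSeries, zero_policy="half-min") -> GroupSeries:
    """Fill R_t = ln(N'_t) - ln(N'_{t-1}) for consecutive year pairs.

    ``N'`` is the mean index after the zero policy.  ``growth_rate[i]`` is
    the rate into year ``years[i]``; the first element (and any element
    following a gap) is NaN.
    """
    if len(series) < 2:
        raise ValueError(f"group {series.group_id}: need >= 2 years for growth rates")
    n = apply_zero_policy(series.mean_index, zero_policy)
    with np.errstate(divide="ignore"):
        logn = np.log(n)
    r = np.full(len(series), np.nan)
    consecutive = np.diff(series.years) == 1
    r[1:][consecutive] = np.diff(logn)[consecutive]
    if zero_policy == "drop":
        r[~np.isfinite(r)] = np.nan
    if not np.isfinite(r[1:][consecutive]).all() and zero_policy != "drop":
        raise ValueError(f"group {series.group_id}: non-finite growth rate after zero policy")
    return GroupSeries(
        series.group_id, series.member_transect_ids, series.years, series.mean_index, r
    )


def eligible_series(series_list: list[GroupSeries], min_steps: int = 3) -> list[GroupSeries]:
    """Consecutive runs with strictly more than ``min_steps`` observations.

    Splits each input series at year gaps first, mirroring the requirement
    that the feedback diagnostics only see gap-free series.
    """
    out: list[GroupSeries] = []
    for s in series_list:
        for run in s.runs():
            if len(run) > min_steps:
                out.append(run)
    return out


def series_to_frame(series_list: list[GroupSeries]) -> pd.DataFrame:
    """Long-format table (group_id, year, mean_index, growth_rate) for export."""
    rows = []
    for s in series_list:
        r = s.growth_rate if s.growth_rate is not None else np.full(len(s), np.nan)
        for y, n, g in zip(s.years, s.mean_index, r):
            rows.append((s.group_id, int(y), float(n), float(g)))
    return pd.DataFrame(rows, columns=["group_id", "year", "mean_index", "growth_rate"])
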