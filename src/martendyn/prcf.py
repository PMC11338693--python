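"""Partial Rate Correlation Function (PRCF) density-dependence diagnosis.

With X_t = ln N_t and realized per-capita rate of change R_t = X_t - X_{t-1},
PRCF(d) is the partial correlation between R_t and X_{t-d} controlling for
the intermediate lags X_{t-1}, ..., X_{t-(d-1)} (at d = 1 it is the plain
Pearson correlation of R_t with X_{t-1}).  The smallest lag whose
coefficient is negative and exceeds Bartlett's approximate 95% band
(+-2/sqrt(n)) estimates the order of density-dependent feedback: order 1 is
direct density dependence, order >= 2 is the delayed feedback signature of
cyclic dynamics.  Partial correlations are computed by correlating the
residuals of the two controlling OLS regressions, which is numerically
stable for the short series this diagnostic is designed for.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .indices import apply_zero_policy


@dataclass
class PrcfResult:
    """PRCF coefficients and feedback-order classification for one series."""

    series_id: str
    n: int                       # effective length of the consecutive series
    max_lag: int
    coefficients: np.ndarray     # PRCF(d), d = 1..max_lag
    band: float                  # Bartlett threshold 2/sqrt(n)
    regression_residuals: np.ndarray  # residuals of the lag-1 rate regression
    mean_abs_residual: float     # summary: small values = marginal change
    inferred_order: int | None   # smallest significant negative lag, or None
    argmin_lag: int              # lag of the most negative coefficient

    @property
    def significant(self) -> np.ndarray:
        return np.abs(self.coefficients) > self.band


def bartlett_band(n: int) -> float:
    """Bartlett's approximate 95% significance band 2/sqrt(n) for a length-n series."""
    if n < 4:
        raise ValueError("Bartlett band requires effective length n >= 4")
    return 2.0 / np.sqrt(n)


def _ols_residuals(y: np.ndarray, Z: np.ndarray) -> np.ndarray:
    """Residuals of y on [1, Z] via least squares."""
    A = np.column_stack([np.ones(len(y)), Z]) if Z.size else np.ones((len(y), 1))
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    return y - A @ coef


def prcf(
    series,
    max_lag: int | None = None,
    zero_policy="half-min",
    series_id: str = "series",
) -> PrcfResult:
    """Compute PRCF(d) for d = 1..max_lag on a consecutive abundance series.

    ``series`` is the N_t sequence (non-negative; the zero policy of the
    index module makes it strictly positive before logging).  ``max_lag``
    defaults to floor(length / 3) capped at 5 and is truncated (with a
    warning) when the series is too short for the request.
    """
    n_t = np.asarray(series, dtype=float)
    if n_t.ndim != 1:
        raise ValueError("series must be 1-d")
    T = len(n_t)
    if max_lag is None:
        max_lag = min(5, T // 3)
    if max_lag < 1:
        raise ValueError(f"series too short for PRCF (length {T})")
    if T < max_lag + 3:
        new_max = T - 3
        if new_max < 1:
            raise ValueError(f"series too short for PRCF (length {T})")
        warnings.warn(
            f"{series_id}: length {T} too short for max_lag {max_lag}; truncating to {new_max}",
            stacklevel=2,
        )
        max_lag = new_max

    X = np.log(apply_zero_policy(n_t, zero_policy))
    if not np.isfinite(X).all():
        raise ValueError(f"{series_id}: non-finite log abundance (check the zero policy)")
    R = np.diff(X)  # R[t-1] = X_t - X_{t-1}, t = 1..T-1
    n_eff = T       # Bartlett's criterion is stated for a length-n series

    coeffs = np.empty(max_lag)
    for d in range(1, max_lag + 1):
        # rows t = d..T-1: response R_t, target X_{t-d}, controls X_{t-1..t-d+1}
        t = np.arange(d, T)
        y = R[t - 1]
        target = X[t - d]
        controls = np.column_stack([X[t - j] for j in range(1, d)]) if d > 1 else np.empty((len(t), 0))
        ry = _ols_residuals(y, controls)
        rx = _ols_residuals(target, controls)
        denom = np.sqrt((ry**2).sum() * (rx**2).sum())
        coeffs[d - 1] = float(ry @ rx / denom) if denom > 0 else 0.0

    band = bartlett_band(n_eff)
    t1 = np.arange(1, T)
    residuals = _ols_residuals(R[t1 - 1], X[t1 - 1][:, None])

    significant_neg = np.flatnonzero((coeffs < 0) & (np.abs(coeffs) > band))
    inferred = int(significant_neg[0] + 1) if significant_neg.size else None
    return PrcfResult(
        series_id=series_id,
        n=n_eff,
        max_lag=max_lag,
        coefficients=coeffs,
        band=band,
        regression_residuals=residuals,
        mean_abs_residual=float(np.mean(np.abs(residuals))),
        inferred_order=inferred,
        argmin_lag=int(np.argmin(coeffs) + 1),
    )


def classify_feedback(results: list[PrcfResult]) -> dict:
    """Summarise feedback order across series.

    Returns a dict with a per-series table and aggregate counts: how many
    series put their most negative coefficient at lag 1 (the direct
    density-dependence majority statistic) and counts per inferred order.
    """
    if not results:
        raise ValueError("no PRCF results to classify")
    table = pd.DataFrame(
        {
            "series_id": [r.series_id for r in results],
            "n": [r.n for r in results],
            "inferred_order": [r.inferred_order for r in results],
            "argmin_lag": [r.argmin_lag for r in results],
            "prcf1": [float(r.coefficients[0]) for r in results],
            "band": [r.band for r in results],
        }
    )
    argmin_counts = table["argmin_lag"].value_counts().sort_index()
    order_counts = (
        table["inferred_order"].value_counts(dropna=False).sort_index(na_position="last")
    )
    return {
        "per_series": table,
        "n_series": len(results),
        "n_argmin_lag1": int((table["argmin_lag"] == 1).sum()),
        "argmin_lag_counts": {str(int(k)): int(v) for k, v in argmin_counts.items()},
        "order_counts": {
            ("none" if pd.isna(k) else str(int(k))): int(v) for k, v in order_counts.items()
        },
    }
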