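"""Seasonal migration analysis: annual harmonics, circular phase, binned means.

North--south seasonal migrations appear in the meridional DC-trajectory as
a near-sinusoidal annual oscillation.  Each trajectory's amplitude and
phase are extracted by least-squares fitting of a fixed-period
(365.25-day) sine with an offset and a linear trend (the trend absorbs
non-seasonal meridional drift); the population phase is summarized by a
circular mean of the peak days-of-year.  Complementary discrete views:
mean meridional DC-velocity in [1 deg latitude x 7 day] boxes, day-of-year
mean meridional velocities integrated into an annual mean trajectory, and
season-mean DC-velocity vectors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .kinematics import DCSeries, KM_PER_DAY_PER_MS

logger = logging.getLogger(__name__)

YEAR_DAYS = 365.25
OMEGA = 2.0 * np.pi / YEAR_DAYS  # rad / day


@dataclass
class SeasonalFit:
    """Annual sine fit of one meridional DC-trajectory (km, days)."""

    id: str
    amplitude_km: float
    peak_doy: float  # fractional day-of-year of the sine maximum, in [0, 366)
    offset_km: float
    trend_km_per_day: float
    rms_residual_km: float
    eligible: bool  # track spans more than one year
    reliable: bool = True


def fit_annual_sine(series: DCSeries, trend: bool = True) -> SeasonalFit:
    """Fit ``y_dc(t) = c + b t + A sin(w t + theta)`` with w fixed at 2*pi/365.25 d.

    Linear in (c, b, A cos(theta), A sin(theta)), solved by least squares;
    the reported amplitude is nonnegative and the phase is reported as the
    fractional day-of-year at which the sine component peaks.  ``eligible``
    marks tracks longer than a year, on which amplitude and phase are well
    constrained; ill-conditioned designs (short tracks) are flagged
    ``reliable=False``.
    """
    if series.y_dc is None:
        raise ValueError("run dc_trajectory first")
    valid = np.isfinite(series.y_dc)
    if valid.sum() < 30:
        raise ValueError("need at least 30 daily y_dc values")
    t0 = series.dates[0]
    t = ((series.dates - t0) / pd.Timedelta(days=1)).to_numpy(float)[valid]
    y = series.y_dc[valid]

    cols = [np.ones_like(t), np.cos(OMEGA * t), np.sin(OMEGA * t)]
    if trend:
        cols.insert(1, t)
    X = np.column_stack(cols)
    beta, _, rank, sv = np.linalg.lstsq(X, y, rcond=None)
    reliable = (rank == X.shape[1]) and (sv[0] / max(sv[-1], 1e-300) < 1e8)

    if trend:
        c, b, P, Q = beta
    else:
        (c, P, Q), b = beta, 0.0
    A = float(np.hypot(P, Q))
    # P cos(wt) + Q sin(wt) = A sin(wt + theta), theta = atan2(P, Q)
    theta = np.arctan2(P, Q)
    t_peak = ((np.pi / 2.0 - theta) % (2.0 * np.pi)) / OMEGA  # days after t0
    peak_date = t0 + pd.Timedelta(days=float(t_peak))
    frac = (peak_date - peak_date.normalize()) / pd.Timedelta(days=1)
    peak_doy = float((peak_date.dayofyear + frac) % 366)

    resid = y - X @ beta
    span = t[-1] - t[0]
    return SeasonalFit(
        id=series.id,
        amplitude_km=A,
        peak_doy=peak_doy,
        offset_km=float(c),
        trend_km_per_day=float(b),
        rms_residual_km=float(np.sqrt(np.mean(resid ** 2))),
        eligible=bool(span > 365.0),
        reliable=bool(reliable),
    )


def circular_mean_phase(doys) -> tuple[float, float]:
    """Circular mean of day-of-year phases.

    Accepts an iterable of day-of-year values (or SeasonalFit objects).
    Returns ``(mean_doy, resultant_length)`` with the mean as a fractional
    day-of-year; raises when the phases cancel (resultant ~ 0), where a
    mean direction is undefined.
    """
    vals = np.array([
        d.peak_doy if isinstance(d, SeasonalFit) else float(d) for d in doys
    ])
    if len(vals) == 0:
        raise ValueError("need at least one phase")
    ang = 2.0 * np.pi * vals / YEAR_DAYS
    C, S = np.mean(np.cos(ang)), np.mean(np.sin(ang))
    R = float(np.hypot(C, S))
    if R < 1e-6:
        raise ValueError("phases are balanced; circular mean undefined")
    mean_doy = float((np.arctan2(S, C) % (2.0 * np.pi)) * YEAR_DAYS / (2.0 * np.pi))
    return mean_doy, R


def doy_to_date(doy: float, year: int = 2001) -> pd.Timestamp:
    """Convenience: map a (fractional) day-of-year to a calendar date."""
    return pd.Timestamp(year=year, month=1, day=1) + pd.Timedelta(days=float(doy) - 1)


def binned_meridional_means(
    day_table: pd.DataFrame, min_count: int = 50
) -> pd.DataFrame:
    """Mean meridional DC-velocity in [1 deg latitude x 7 day] boxes.

    ``day_table`` pools per-day rows with columns ``lat, doy, v_dc`` (see
    :func:`dcswim.segmentation.segment_day_table`).  Cells supported by
    ``min_count`` samples or fewer are masked (mean set to NaN), keeping
    only robustly estimated cells, but their counts are still reported.
    """
    df = day_table.dropna(subset=["lat", "v_dc"]).copy()
    df["lat_bin"] = np.floor(df["lat"]).astype(int)
    df["week"] = ((df["doy"].astype(int) - 1) // 7 + 1).clip(upper=53)
    g = df.groupby(["lat_bin", "week"])
    out = g.agg(mean_v_dc=("v_dc", "mean"), n=("v_dc", "size")).reset_index()
    out.loc[out["n"] <= min_count, "mean_v_dc"] = np.nan
    return out


def annual_mean_meridional_trajectory(day_table: pd.DataFrame) -> pd.DataFrame:
    """Day-of-year mean meridional DC-velocity integrated over a calendar year.

    Pools every day (weighting each segment-day equally), averages v_dc per
    day-of-year 1..365 (day 366 folded into 365), linearly gap-fills empty
    days (logged), and integrates from January 1 to December 31.  Returns a
    frame with ``doy, mean_v_dc, n, y_km``; the annual migration distance
    is ``max(y_km) - min(y_km)``.
    """
    df = day_table.dropna(subset=["v_dc"]).copy()
    doy = np.minimum(df["doy"].astype(int), 365)
    mean_v = np.full(365, np.nan)
    counts = np.zeros(365, dtype=int)
    g = df.groupby(doy)["v_dc"]
    agg = g.agg(["mean", "size"])
    mean_v[agg.index.to_numpy() - 1] = agg["mean"].to_numpy()
    counts[agg.index.to_numpy() - 1] = agg["size"].to_numpy()

    empty = ~np.isfinite(mean_v)
    if empty.any():
        logger.warning("gap-filling %d empty days of year", int(empty.sum()))
        idx = np.arange(365)
        mean_v = np.interp(idx, idx[~empty], mean_v[~empty], period=365)

    y_km = np.concatenate([[0.0], np.cumsum(mean_v[:-1]) * KM_PER_DAY_PER_MS])
    return pd.DataFrame({
        "doy": np.arange(1, 366), "mean_v_dc": mean_v, "n": counts, "y_km": y_km,
    })


def migration_distance_km(annual: pd.DataFrame) -> float:
    """Peak-to-trough excursion of the annual mean meridional DC-trajectory."""
    y = annual["y_km"].to_numpy()
    y_end = y[-1] + annual["mean_v_dc"].to_numpy()[-1] * KM_PER_DAY_PER_MS
    full = np.append(y, y_end)
    return float(full.max() - full.min())


_SEASONS = {
    "DJF": (12, 1, 2), "MAM": (3, 4, 5), "JJA": (6, 7, 8), "SON": (9, 10, 11),
}


def seasonal_vectors(day_table: pd.DataFrame) -> pd.DataFrame:
    """Season-mean DC-velocity vectors (meteorological seasons).

    Returns one row per season with ``mean_u_dc, mean_v_dc, n``; empty
    seasons are absent.
    """
    df = day_table.dropna(subset=["u_dc", "v_dc"]).copy()
    month = pd.DatetimeIndex(df["date"]).month
    rows = []
    for season, months in _SEASONS.items():
        sel = df[np.isin(month, months)]
        if len(sel) == 0:
            continue
        rows.append({
            "season": season,
            "mean_u_dc": float(sel["u_dc"].mean()),
            "mean_v_dc": float(sel["v_dc"].mean()),
            "n": len(sel),
        })
    return pd.DataFrame(rows)
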