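"""Drift-corrected (DC) velocities, DC-trajectories and ensemble statistics.

The DC-velocity is the velocity over ground minus the modeled drift
velocity: for an animal it estimates the swimming velocity, for a passive
drifter it *is* the drift-estimation noise.  Its time integral, the
DC-trajectory, lives in a local (x, y) plane starting at (0, 0) — it is a
cumulative swimming displacement, not a position on the Earth's surface —
and turns slow persistent swimming into a large, easily measured signal
(1 cm/s sustained for a year is more than 300 km).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .leeway import DriftModel
from .tracks import DailyTrack, SECONDS_PER_DAY

logger = logging.getLogger(__name__)

#: km of DC displacement per day per (m/s) of DC-velocity
KM_PER_DAY_PER_MS = SECONDS_PER_DAY / 1000.0


@dataclass
class DCSeries:
    """Daily DC-velocity components and cumulative DC-trajectory.

    ``x_dc``/``y_dc`` are in km with origin (0, 0) on the first day
    (``origin_mode="release"``); ``lat`` and ``scl`` are carried along for
    the seasonal and size analyses when available.
    """

    id: str
    dates: pd.DatetimeIndex
    u_dc: np.ndarray
    v_dc: np.ndarray
    x_dc: np.ndarray | None = None
    y_dc: np.ndarray | None = None
    lat: np.ndarray | None = None
    scl: np.ndarray | None = None
    group: str = "synthetic"
    origin_mode: str = "release"
    n_missing: int = 0

    def __len__(self) -> int:
        return len(self.dates)

    @property
    def final_x(self) -> float:
        """Zonal DC displacement (km) after the last day's increment."""
        inc = 0.0 if np.isnan(self.u_dc[-1]) else self.u_dc[-1] * KM_PER_DAY_PER_MS
        return float(self.x_dc[-1] + inc)

    @property
    def final_y(self) -> float:
        """Meridional DC displacement (km) after the last day's increment."""
        inc = 0.0 if np.isnan(self.v_dc[-1]) else self.v_dc[-1] * KM_PER_DAY_PER_MS
        return float(self.y_dc[-1] + inc)


def dc_velocity(track: DailyTrack, model: DriftModel) -> DCSeries:
    """Per-day DC-velocity ``V_g - (V_co + gamma * V_sto)``.

    Days missing the velocity over ground or either matched field stay
    missing.  Also stores ``u_dc``/``v_dc`` on the track for CSV round-trips.
    """
    d = track.data
    u = (d["vg_u"] - (d["vco_u"] + model.gamma * d["vsto_u"])).to_numpy(float)
    v = (d["vg_v"] - (d["vco_v"] + model.gamma * d["vsto_v"])).to_numpy(float)
    d["u_dc"], d["v_dc"] = u, v
    scl = d["scl"].to_numpy(float) if "scl" in d.columns else None
    return DCSeries(
        id=track.id, dates=track.dates, u_dc=u, v_dc=v,
        lat=track.lat.copy(), scl=scl, group=track.group,
    )


def dc_trajectory(series: DCSeries) -> DCSeries:
    """Integrate DC-velocity into the cumulative plane DC-trajectory (km).

    ``x_dc[0] = y_dc[0] = 0``; each day's velocity contributes one daily
    increment.  Missing velocity days contribute zero displacement but are
    counted in ``n_missing`` (silent interpolation would bias the result).
    """
    inc_x = np.nan_to_num(series.u_dc, nan=0.0) * KM_PER_DAY_PER_MS
    inc_y = np.nan_to_num(series.v_dc, nan=0.0) * KM_PER_DAY_PER_MS
    series.n_missing = int(np.isnan(series.u_dc).sum())
    series.x_dc = np.concatenate([[0.0], np.cumsum(inc_x[:-1])])
    series.y_dc = np.concatenate([[0.0], np.cumsum(inc_y[:-1])])
    return series


def attach_to_track(track: DailyTrack, series: DCSeries) -> DailyTrack:
    """Store the DC-trajectory on the track frame (``x_dc_km``, ``y_dc_km``)."""
    track.data["x_dc_km"] = series.x_dc
    track.data["y_dc_km"] = series.y_dc
    return track


def ensemble_stats(
    series_list: list[DCSeries],
    origin_mode: str = "release",
    min_n: int = 20,
) -> pd.DataFrame:
    """Per-elapsed-day ensemble mean and std of x_dc and y_dc.

    ``origin_mode="release"`` aligns series on their first day;
    ``"calendar_jan1"`` shifts each series so elapsed day 0 is January 1 of
    its release year (seasonal signals then align across individuals).
    Rows where fewer than ``min_n`` series are alive are masked (NaN),
    following the convention of discontinuing ensemble curves once the
    sample gets thin.
    """
    offsets = []
    for s in series_list:
        if s.x_dc is None:
            raise ValueError(f"series {s.id}: run dc_trajectory first")
        if origin_mode == "release":
            off = 0
        elif origin_mode == "calendar_jan1":
            jan1 = pd.Timestamp(year=s.dates[0].year, month=1, day=1)
            off = int((s.dates[0].normalize() - jan1).days)
        else:
            raise ValueError(f"unknown origin_mode {origin_mode!r}")
        offsets.append(off)

    horizon = max(off + len(s) for off, s in zip(offsets, series_list))
    X = np.full((len(series_list), horizon), np.nan)
    Y = np.full((len(series_list), horizon), np.nan)
    for k, (off, s) in enumerate(zip(offsets, series_list)):
        X[k, off:off + len(s)] = s.x_dc
        Y[k, off:off + len(s)] = s.y_dc
    count = np.isfinite(X).sum(axis=0)
    import warnings
    with warnings.catch_warnings(), np.errstate(invalid="ignore", divide="ignore"):
        warnings.simplefilter("ignore", category=RuntimeWarning)
        mean_x = np.nanmean(X, axis=0)
        mean_y = np.nanmean(Y, axis=0)
        std_x = np.nanstd(X, axis=0, ddof=1)
        std_y = np.nanstd(Y, axis=0, ddof=1)
    std_x = np.where(count >= 2, std_x, np.nan)
    std_y = np.where(count >= 2, std_y, np.nan)
    out = pd.DataFrame({
        "elapsed_day": np.arange(horizon),
        "n": count,
        "mean_x": mean_x, "std_x": std_x,
        "mean_y": mean_y, "std_y": std_y,
    })
    thin = count < min_n
    out.loc[thin, ["mean_x", "std_x", "mean_y", "std_y"]] = np.nan
    return out


def noise_maps(
    tracks: list[DailyTrack],
    gamma: float = 0.0,
) -> pd.DataFrame:
    """DC-velocity samples of passive drifters for box-averaged noise maps.

    Computes drifter DC-velocities under the stated model variant
    (``gamma=0``: drift is the Eulerian current alone; ``gamma=0.88``-like:
    leeway-corrected) and returns a ``(lat, lon, u, v)`` frame ready for
    :func:`dcswim.fields.box_statistics`.  Contrasting the two variants maps
    the error pattern that the leeway term removes.
    """
    model = DriftModel(gamma=gamma)
    rows = []
    for tr in tracks:
        s = dc_velocity(tr, model)
        rows.append(pd.DataFrame({
            "lat": tr.lat, "lon": tr.lon, "u": s.u_dc, "v": s.v_dc,
        }))
    return pd.concat(rows, ignore_index=True)
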