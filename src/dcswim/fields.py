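"""Gridded surface current and Stokes-drift fields: containers, sampling, matching.

Fields follow the CF-style layout of operational reanalysis products
(regular lat/lon axes, daily time axis, variables ``uo``/``vo`` for the
0--1 m Eulerian current and ``vsdx``/``vsdy`` for the surface Stokes
drift), so downloaded reanalysis files are drop-in replacements for the
synthetic ones.  Longitudes are stored in [0, 360) internally: the study
basin (120E--110W) straddles the antimeridian and a [-180, 180) axis would
put a seam through the middle of it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import xarray as xr

logger = logging.getLogger(__name__)

CURRENT_VARS = ("uo", "vo")
STOKES_VARS = ("vsdx", "vsdy")


def _check_axis(ax: np.ndarray, name: str) -> float:
    step = np.diff(ax)
    if len(step) == 0:
        raise ValueError(f"{name} axis needs at least 2 nodes")
    if np.any(step <= 0):
        raise ValueError(f"{name} axis must be strictly increasing")
    if np.ptp(step) > 1e-6:
        raise ValueError(f"{name} axis must be uniform to 1e-6 degree")
    return float(step.mean())


@dataclass
class GriddedFieldSet:
    """Daily 2-component vector fields (current + Stokes) on a regular grid.

    ``steady=True`` marks a single time slice valid for every date (used by
    the synthetic climatological fields); otherwise the dataset carries a
    daily ``time`` axis and each track day is matched to its own slice.
    """

    ds: xr.Dataset
    steady: bool = False

    def __post_init__(self):
        lon = self.ds["lon"].to_numpy()
        if np.any(lon < 0):  # normalize to [0, 360)
            self.ds = self.ds.assign_coords(lon=(lon % 360.0)).sortby("lon")
        self.dlat = _check_axis(self.ds["lat"].to_numpy(), "lat")
        self.dlon = _check_axis(self.ds["lon"].to_numpy(), "lon")
        for v in CURRENT_VARS + STOKES_VARS:
            if v not in self.ds:
                raise ValueError(f"fieldset missing variable {v!r}")

    @property
    def lat_axis(self) -> np.ndarray:
        return self.ds["lat"].to_numpy()

    @property
    def lon_axis(self) -> np.ndarray:
        return self.ds["lon"].to_numpy()

    @property
    def time_axis(self) -> pd.DatetimeIndex:
        if self.steady or "time" not in self.ds.dims:
            return pd.DatetimeIndex([])
        return pd.DatetimeIndex(self.ds["time"].to_numpy())

    def to_netcdf(self, path) -> None:
        ds = self.ds.copy()
        ds.attrs["steady"] = int(self.steady)
        ds.to_netcdf(path, engine="scipy")

    @classmethod
    def from_netcdf(cls, path) -> "GriddedFieldSet":
        ds = xr.load_dataset(path, engine="scipy")
        steady = bool(ds.attrs.get("steady", 0))
        return cls(ds=ds, steady=steady)

    # -- sampling -----------------------------------------------------------

    def _time_index(self, dates) -> np.ndarray:
        """Map dates to time-axis indices; -1 where the day is absent."""
        if self.steady or "time" not in self.ds.dims:
            return np.zeros(len(dates), dtype=int)
        axis = pd.DatetimeIndex(self.ds["time"].to_numpy()).normalize()
        want = pd.DatetimeIndex(dates).normalize()
        pos = axis.get_indexer(want)
        return pos

    def contains(self, lat, lon) -> np.ndarray:
        """Boolean mask of points inside the spatial grid hull."""
        lat = np.atleast_1d(np.asarray(lat, float))
        lon = np.atleast_1d(np.asarray(lon, float)) % 360.0
        la, lo = self.lat_axis, self.lon_axis
        return (lat >= la[0]) & (lat <= la[-1]) & (lon >= lo[0]) & (lon <= lo[-1])

    def sample(self, kind: str, dates, lat, lon):
        """Bilinearly sample a field along (date, lat, lon) points.

        Parameters
        ----------
        kind : "current" or "stokes"

        Returns (u, v) arrays in m/s; NaN where the day is off the time
        axis or all four surrounding nodes are masked.  Raises ValueError
        for points outside the spatial grid hull.
        """
        names = CURRENT_VARS if kind == "current" else STOKES_VARS
        lat = np.atleast_1d(np.asarray(lat, float))
        lon = np.atleast_1d(np.asarray(lon, float)) % 360.0
        dates = pd.DatetimeIndex(np.atleast_1d(dates))
        ti = self._time_index(dates)

        la, lo = self.lat_axis, self.lon_axis
        inside = (lat >= la[0]) & (lat <= la[-1]) & (lon >= lo[0]) & (lon <= lo[-1])
        if not inside.all():
            k = int(np.flatnonzero(~inside)[0])
            raise ValueError(
                f"point (lat={lat[k]:.3f}, lon={lon[k]:.3f}) outside grid hull"
            )

        i0 = np.clip(((lat - la[0]) / self.dlat).astype(int), 0, len(la) - 2)
        j0 = np.clip(((lon - lo[0]) / self.dlon).astype(int), 0, len(lo) - 2)
        fy = (lat - la[i0]) / self.dlat
        fx = (lon - lo[j0]) / self.dlon
        w = np.stack([(1 - fy) * (1 - fx), (1 - fy) * fx, fy * (1 - fx), fy * fx])

        out = []
        ok_time = ti >= 0
        if not hasattr(self, "_arrays"):
            self._arrays = {}
        for name in names:
            arr = self._arrays.get(name)
            if arr is None:
                arr = self.ds[name].to_numpy()
                if arr.ndim == 2:
                    arr = arr[None, ...]
                self._arrays[name] = arr
            t = np.where(ok_time, ti, 0)
            corners = np.stack([
                arr[t, i0, j0], arr[t, i0, j0 + 1],
                arr[t, i0 + 1, j0], arr[t, i0 + 1, j0 + 1],
            ])
            valid = np.isfinite(corners)
            wv = np.where(valid, w, 0.0)
            wsum = wv.sum(axis=0)
            with np.errstate(invalid="ignore"):
                val = np.where(
                    wsum > 0,
                    np.nansum(wv * np.where(valid, corners, 0.0), axis=0) / wsum,
                    np.nan,
                )
            val = np.where(ok_time, val, np.nan)
            out.append(val)
        return out[0], out[1]


def sample_bilinear(fields: GriddedFieldSet, kind: str, date, lat, lon):
    """Sample one point; thin wrapper over :meth:`GriddedFieldSet.sample`."""
    u, v = fields.sample(kind, [date], [lat], [lon])
    return float(u[0]), float(v[0])


def daily_average(ds: xr.Dataset) -> xr.Dataset:
    """Average sub-daily field slices to daily (0:00--24:00 UTC) means.

    Days of the target range with no slices at all are dropped (logged),
    not NaN-filled.
    """
    out = ds.resample(time="1D").mean()
    slices = ds["uo"].resample(time="1D").count()
    while slices.ndim > 1:
        slices = slices.max(dim=slices.dims[-1])
    vals = slices.to_numpy().astype(float)
    empty = ~(vals > 0)  # NaN or 0 slices both mean an empty day
    if empty.any():
        logger.warning("dropping %d days with no sub-daily slices", int(empty.sum()))
        out = out.isel(time=~empty)
    return out


def match_fields(track, fields: GriddedFieldSet):
    """Fill ``vco_*`` and ``vsto_*`` by sampling both fields at each day's noon fix.

    Returns ``(track, n_matched, n_unmatched)``; days off the field time
    axis stay missing.  A fully unmatched track is logged as a warning.
    """
    dates = track.dates
    lat, lon = track.lat, track.lon
    inside = fields.contains(lat, lon)
    if not inside.all():
        logger.warning(
            "track %s: %d positions outside the field hull left unmatched",
            track.id, int((~inside).sum()),
        )
    n = len(track)
    u_co = np.full(n, np.nan); v_co = np.full(n, np.nan)
    u_st = np.full(n, np.nan); v_st = np.full(n, np.nan)
    if inside.any():
        u_co[inside], v_co[inside] = fields.sample(
            "current", dates[inside], lat[inside], lon[inside])
        u_st[inside], v_st[inside] = fields.sample(
            "stokes", dates[inside], lat[inside], lon[inside])
    track.data["vco_u"], track.data["vco_v"] = u_co, v_co
    track.data["vsto_u"], track.data["vsto_v"] = u_st, v_st
    matched = int(np.isfinite(u_co).sum())
    if matched == 0 and len(track) > 0:
        logger.warning("track %s: no days matched the field time axis", track.id)
    return track, matched, len(track) - matched


def box_statistics(samples: pd.DataFrame, box: float = 5.0) -> pd.DataFrame:
    """Per-box mean vector and std of the vector norm.

    ``samples`` needs columns ``lat, lon, u, v``; rows with any NaN are
    dropped.  Returns one row per populated ``box`` x ``box`` degree cell
    (keyed by the cell's SW corner): component-wise mean vector, the
    standard deviation of the norm of the individual vectors (population
    std, as a noise magnitude), and the sample count.
    """
    df = samples.dropna(subset=["lat", "lon", "u", "v"]).copy()
    df["lon"] = df["lon"].to_numpy() % 360.0
    df["lat0"] = np.floor(df["lat"] / box) * box
    df["lon0"] = np.floor(df["lon"] / box) * box
    df["norm"] = np.hypot(df["u"], df["v"])
    g = df.groupby(["lat0", "lon0"])
    out = g.agg(
        mean_u=("u", "mean"),
        mean_v=("v", "mean"),
        std_norm=("norm", lambda x: float(np.std(x))),
        n=("u", "size"),
    ).reset_index()
    return out
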