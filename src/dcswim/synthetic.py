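"""Seedable synthetic basin: gridded fields, passive drifters, programmed turtles.

Everything the estimators consume can be generated here with known ground
truth, emulating the North Pacific study system without any data download:

* a basin [20--55N; 120E--110W] with an eastward zonal jet of 4--11 cm/s
  between 30--45N strengthening towards the western boundary, and a
  clockwise surface Stokes-drift gyre of ~5 cm/s;
* undrogued-buoy-like drifters advected daily by
  ``V_co + gamma * V_sto + noise`` (gamma = 0.88), reported with ~1 km
  Argos-like position noise;
* juvenile-turtle-like tracks adding a swimming velocity: an annual
  meridional sinusoid whose *positional* peak falls on a configured date
  (default Sept 21, the fall equinox), an isotropic foraging random walk,
  and a sustained westward homing component switched on when the imputed
  size crosses a per-individual threshold drawn around 42 cm.

Truth tables store noise-free positions, the planted swimming velocity and
the trigger, so every estimator can be scored against what was planted.
Identical config + seed gives bit-identical outputs.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd
import xarray as xr

from . import growth as growth_mod
from .fields import GriddedFieldSet
from .growth import GrowthParams, scl_at
from .kinematics import DCSeries, dc_trajectory
from .seasonal import YEAR_DAYS, OMEGA
from .tracks import (
    DailyTrack, SECONDS_PER_DAY,
    meters_per_degree_lat, meters_per_degree_lon,
)


@dataclass
class SyntheticConfig:
    """Study conditions of the synthetic basin (defaults are the reference run)."""

    lat_range: tuple[float, float] = (20.0, 55.0)
    lon_range: tuple[float, float] = (120.0, 250.0)  # 120E to 110W, continuous
    grid_step: float = 0.5
    start_date: str = "2005-01-01"

    n_drifters: int = 200
    n_turtles: int = 60
    drifter_days: int = 300
    turtle_days: int = 730

    gamma_drifter: float = 0.88
    gamma_turtle: float = 0.28

    # zonal jet: eastward, 0.04 m/s at the eastern edge to 0.11 near Japan
    current_east_range: tuple[float, float] = (0.04, 0.11)
    current_band: tuple[float, float] = (30.0, 45.0)
    stokes_magnitude: float = 0.05  # max |u_sto| of the clockwise gyre

    # swimming program
    seasonal_amplitude_velocity: float = 0.0876  # m/s; ~440 km positional amplitude
    peak_doy: float = 264.0  # Sept 21: positional (not velocity) maximum
    homing_speed_range: tuple[float, float] = (0.09, 0.15)  # m/s at 35 / 55+ cm SCL
    trigger_scl_mean: float = 42.0
    trigger_scl_sd: float = 4.0
    foraging_rw_std: float = 0.02  # m/s, isotropic

    process_noise_std: float = 0.03  # m/s, drifter sub-grid velocity noise
    argos_noise_std_m: float = 1000.0  # per-component reported-position noise

    release_box_drifters: tuple[tuple[float, float], tuple[float, float]] = (
        (25.0, 48.0), (135.0, 235.0))
    release_box_turtles: tuple[tuple[float, float], tuple[float, float]] = (
        (28.0, 40.0), (150.0, 200.0))
    release_scl_mean: float = 36.0
    release_scl_sd: float = 5.0
    #: releases are staggered over this window (monthly cohorts), as real
    #: deployments span seasons and years; 0 = single shared release date
    release_spread_days: int = 365

    seed: int = 0

    def to_manifest(self) -> dict:
        return dataclasses.asdict(self)


# -- fields -----------------------------------------------------------------

def current_profile(cfg: SyntheticConfig, lat, lon):
    """Analytic zonal-jet current (u, v) in m/s at the given coordinates."""
    lat = np.asarray(lat, float)
    lon = np.asarray(lon, float)
    lo0, lo1 = cfg.lon_range
    e_east, e_west = cfg.current_east_range
    amp = e_west - (e_west - e_east) * (lon - lo0) / (lo1 - lo0)
    b0, b1 = cfg.current_band
    center = 0.5 * (b0 + b1)
    half = 0.5 * (b1 - b0)
    shape = np.exp(-(((lat - center) / half) ** 4))  # flat-topped jet
    return amp * shape, np.zeros_like(amp * shape)


def stokes_profile(cfg: SyntheticConfig, lat, lon):
    """Analytic clockwise Stokes gyre (u, v) in m/s; linear in lat and lon."""
    lat = np.asarray(lat, float)
    lon = np.asarray(lon, float)
    la0, la1 = cfg.lat_range
    lo0, lo1 = cfg.lon_range
    lat_c, lon_c = 0.5 * (la0 + la1), 0.5 * (lo0 + lo1)
    u = cfg.stokes_magnitude * (lat - lat_c) / (0.5 * (la1 - la0))
    v = -0.5 * cfg.stokes_magnitude * (lon - lon_c) / (0.5 * (lo1 - lo0))
    return u, v


def gen_fields(cfg: SyntheticConfig) -> GriddedFieldSet:
    """Steady gridded fields evaluating the analytic profiles at the nodes."""
    lat = np.arange(cfg.lat_range[0], cfg.lat_range[1] + cfg.grid_step / 2,
                    cfg.grid_step)
    lon = np.arange(cfg.lon_range[0], cfg.lon_range[1] + cfg.grid_step / 2,
                    cfg.grid_step)
    LAT, LON = np.meshgrid(lat, lon, indexing="ij")
    uo, vo = current_profile(cfg, LAT, LON)
    su, sv = stokes_profile(cfg, LAT, LON)
    ds = xr.Dataset(
        {
            "uo": (("lat", "lon"), uo), "vo": (("lat", "lon"), vo),
            "vsdx": (("lat", "lon"), su), "vsdy": (("lat", "lon"), sv),
        },
        coords={"lat": lat, "lon": lon},
    )
    return GriddedFieldSet(ds=ds, steady=True)


# -- advection --------------------------------------------------------------

def _advect(
    cfg: SyntheticConfig,
    fields: GriddedFieldSet,
    lat0: np.ndarray,
    lon0: np.ndarray,
    dates: pd.DatetimeIndex,
    gamma: float,
    rng: np.random.Generator,
    swim_fn=None,
    process_noise_std: float = 0.0,
):
    """Daily Euler advection of particles; returns (lat, lon, swim_u, swim_v).

    Daily stepping (not RK4) matches the daily-mean cadence of the fields
    and the estimator's own discretization.  Particles leaving the basin
    are truncated (NaN afterwards).  ``swim_fn(day_index, lat, lon, alive)``
    returns the per-particle swimming velocity for the day.
    """
    n = len(lat0)
    T = len(dates)
    lat = np.full((T, n), np.nan)
    lon = np.full((T, n), np.nan)
    s_u = np.zeros((T, n))
    s_v = np.zeros((T, n))
    cur_lat, cur_lon = lat0.copy(), lon0.copy()
    alive = fields.contains(cur_lat, cur_lon)
    for d in range(T):
        lat[d, alive] = cur_lat[alive]
        lon[d, alive] = cur_lon[alive]
        if not alive.any():
            break
        u = np.zeros(n); v = np.zeros(n)
        uc, vc = fields.sample("current", np.repeat(dates[d], alive.sum()),
                               cur_lat[alive], cur_lon[alive])
        us, vs = fields.sample("stokes", np.repeat(dates[d], alive.sum()),
                               cur_lat[alive], cur_lon[alive])
        u[alive] = uc + gamma * us
        v[alive] = vc + gamma * vs
        if swim_fn is not None:
            su, sv = swim_fn(d, cur_lat, cur_lon, alive)
            s_u[d], s_v[d] = su, sv
            u, v = u + su, v + sv
        if process_noise_std > 0:
            u = u + rng.normal(0, process_noise_std, n)
            v = v + rng.normal(0, process_noise_std, n)
        cur_lat = cur_lat + v * SECONDS_PER_DAY / meters_per_degree_lat()
        cur_lon = cur_lon + u * SECONDS_PER_DAY / meters_per_degree_lon(
            np.clip(cur_lat, -89.0, 89.0))
        alive = alive & fields.contains(cur_lat, cur_lon)
    return lat, lon, s_u, s_v


def _report_positions(cfg, lat, lon, rng):
    """Perturb true positions with Argos-like independent per-component noise."""
    sig_lat = cfg.argos_noise_std_m / meters_per_degree_lat()
    sig_lon = cfg.argos_noise_std_m / meters_per_degree_lon(np.nan_to_num(lat, nan=35.0))
    rlat = lat + rng.normal(0, 1, lat.shape) * sig_lat
    rlon = lon + rng.normal(0, 1, lon.shape) * sig_lon
    return rlat, rlon


def _build_tracks(ids, group, dates_list, lat, lon, extra=None, release_scl=None):
    tracks = []
    for j, tid in enumerate(ids):
        ok = np.isfinite(lat[:, j])
        if ok.sum() < 2:
            continue
        idx = dates_list[ok] + pd.Timedelta(hours=12)
        data = pd.DataFrame({"lat": lat[ok, j], "lon": lon[ok, j]}, index=idx)
        if extra:
            for name, arr in extra.items():
                data[name] = arr[ok, j]
        tracks.append(DailyTrack(
            id=tid, data=data, group=group,
            release_scl=None if release_scl is None else float(release_scl[j]),
        ))
    return tracks


def _release_offsets(cfg: SyntheticConfig, n: int,
                     rng: np.random.Generator) -> np.ndarray:
    """Per-individual release-date offsets in days (monthly cohorts)."""
    if cfg.release_spread_days <= 0:
        return np.zeros(n, dtype=int)
    step = max(cfg.release_spread_days // 12, 1)
    return rng.integers(0, 12, n) * step


def gen_drifters(cfg: SyntheticConfig, fields: GriddedFieldSet,
                 rng: np.random.Generator | None = None):
    """Passive drifters obeying ``V_d = V_co + gamma V_sto + noise``.

    Releases are staggered in monthly cohorts over ``release_spread_days``.
    Returns ``(tracks, truth)``: reported-position tracks (group
    ``"drifter"``) and a truth table with the noise-free daily positions
    and the planted gamma.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    n = cfg.n_drifters
    (la0, la1), (lo0, lo1) = cfg.release_box_drifters
    lat0 = rng.uniform(la0, la1, n)
    lon0 = rng.uniform(lo0, lo1, n)
    offsets = _release_offsets(cfg, n, rng)
    ids = np.array([f"drf{j:04d}" for j in range(n)])
    tracks, truths = [], []
    for off in np.unique(offsets):
        sel = offsets == off
        dates = pd.date_range(
            pd.Timestamp(cfg.start_date) + pd.Timedelta(days=int(off)),
            periods=cfg.drifter_days, freq="D")
        lat, lon, _, _ = _advect(cfg, fields, lat0[sel], lon0[sel], dates,
                                 cfg.gamma_drifter, rng,
                                 process_noise_std=cfg.process_noise_std)
        rlat, rlon = _report_positions(cfg, lat, lon, rng)
        tracks += _build_tracks(ids[sel], "drifter", dates, rlat, rlon)
        truths.append(_truth_frame(ids[sel], dates, lat, lon,
                                   gamma_true=cfg.gamma_drifter))
    tracks.sort(key=lambda t: t.id)
    truth = pd.concat(truths, ignore_index=True).sort_values(
        ["id", "date"]).reset_index(drop=True)
    return tracks, truth


def _truth_frame(ids, dates, lat, lon, gamma_true, extras=None):
    T, n = lat.shape
    rec = {
        "id": np.repeat(ids, T),
        "date": np.tile(dates, n),
        "lat_true": lat.T.ravel(),
        "lon_true": lon.T.ravel(),
        "gamma_true": gamma_true,
    }
    if extras:
        for name, arr in extras.items():
            rec[name] = arr.T.ravel()
    df = pd.DataFrame(rec)
    return df[np.isfinite(df["lat_true"])].reset_index(drop=True)


def homing_speed_for_scl(cfg: SyntheticConfig, scl):
    """Westward homing speed, linear in SCL between the configured endpoints."""
    lo, hi = cfg.homing_speed_range
    f = np.clip((np.asarray(scl, float) - 35.0) / (55.0 - 35.0), 0.0, 1.0)
    return lo + (hi - lo) * f


def seasonal_swim_v(cfg: SyntheticConfig, dates) -> np.ndarray:
    """Meridional swimming velocity whose positional peak is ``cfg.peak_doy``.

    Velocity leads position by a quarter period:
    ``v(t) = -A sin(w (doy - peak_doy))`` integrates to a meridional
    excursion peaking on the configured date with amplitude ``A / w``.
    """
    doy = pd.DatetimeIndex(dates).dayofyear.to_numpy(float)
    return -cfg.seasonal_amplitude_velocity * np.sin(OMEGA * (doy - cfg.peak_doy))


def gen_turtles(cfg: SyntheticConfig, fields: GriddedFieldSet,
                rng: np.random.Generator | None = None,
                seasonal: bool = True, homing: bool = True,
                foraging: bool = True):
    """Behaviorally programmed turtles: drift + seasonal sine + size-triggered homing.

    Per individual, the release SCL is drawn around ``release_scl_mean``,
    grown daily by the von Bertalanffy curve; homing (sustained westward
    swimming, speed scaled with size) switches on when SCL crosses a
    per-individual threshold ~ Normal(trigger_scl_mean, trigger_scl_sd).
    Returns ``(tracks, truth, individuals)`` where ``individuals`` holds
    the planted trigger size/date per turtle.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    n = cfg.n_turtles
    (la0, la1), (lo0, lo1) = cfg.release_box_turtles
    lat0_all = rng.uniform(la0, la1, n)
    lon0_all = rng.uniform(lo0, lo1, n)
    l0_all = np.clip(rng.normal(cfg.release_scl_mean, cfg.release_scl_sd, n),
                     25.0, 55.0)
    trigger_all = np.clip(
        rng.normal(cfg.trigger_scl_mean, cfg.trigger_scl_sd, n), 1.0, None)
    offsets = _release_offsets(cfg, n, rng)
    ids_all = np.array([f"ttl{j:04d}" for j in range(n)])

    tracks, truths, ind_rows = [], [], []
    for off in np.unique(offsets):
        sel = offsets == off
        m = int(sel.sum())
        dates = pd.date_range(
            pd.Timestamp(cfg.start_date) + pd.Timedelta(days=int(off)),
            periods=cfg.turtle_days, freq="D")
        l0, trigger = l0_all[sel], trigger_all[sel]
        params = [GrowthParams(l0=float(l), t0=dates[0]) for l in l0]
        scl = np.column_stack([scl_at(p, dates) for p in params])  # (T, m)
        v_season = (seasonal_swim_v(cfg, dates) if seasonal
                    else np.zeros(len(dates)))

        def swim_fn(d, cur_lat, cur_lon, alive):
            su = np.zeros(m)
            sv = np.full(m, v_season[d])
            if homing:
                on = scl[d] >= trigger
                su = np.where(on, -homing_speed_for_scl(cfg, scl[d]), 0.0)
            if foraging and cfg.foraging_rw_std > 0:
                su = su + rng.normal(0, cfg.foraging_rw_std, m)
                sv = sv + rng.normal(0, cfg.foraging_rw_std, m)
            su[~alive] = 0.0
            sv[~alive] = 0.0
            return su, sv

        lat, lon, s_u, s_v = _advect(cfg, fields, lat0_all[sel], lon0_all[sel],
                                     dates, cfg.gamma_turtle, rng,
                                     swim_fn=swim_fn)
        rlat, rlon = _report_positions(cfg, lat, lon, rng)
        tracks += _build_tracks(ids_all[sel], "synthetic", dates, rlat, rlon,
                                release_scl=l0)
        truths.append(_truth_frame(
            ids_all[sel], dates, lat, lon, gamma_true=cfg.gamma_turtle,
            extras={"vs_u": s_u, "vs_v": s_v, "scl": scl}))
        for k, tid in enumerate(ids_all[sel]):
            hit = scl[:, k] >= trigger[k]
            ind_rows.append({
                "id": tid, "release_date": dates[0],
                "release_scl": l0[k], "trigger_scl": trigger[k],
                "trigger_date": dates[int(np.argmax(hit))] if hit.any() else pd.NaT,
            })

    tracks.sort(key=lambda t: t.id)
    truth = pd.concat(truths, ignore_index=True).sort_values(
        ["id", "date"]).reset_index(drop=True)
    individuals = pd.DataFrame(ind_rows).sort_values("id").reset_index(drop=True)
    return tracks, truth, individuals


# -- DC-series level planting (segmentation / seasonal / guard suites) ------

def gen_planted_dh_series(
    n_tracks: int = 100,
    n_days: int = 400,
    switch_day: int = 250,
    drift_mean: float = 0.0,
    homing_mean: float = -0.10,
    noise_std: float = 0.15,
    rng: np.random.Generator | None = None,
    start_date: str = "2005-01-01",
) -> list[DCSeries]:
    """Zonal DC-velocity series with a planted drifting-to-homing switch."""
    if rng is None:
        rng = np.random.default_rng(0)
    dates = pd.date_range(start_date, periods=n_days, freq="D") + pd.Timedelta(hours=12)
    out = []
    for j in range(n_tracks):
        u = np.where(np.arange(n_days) < switch_day, drift_mean, homing_mean)
        u = u + rng.normal(0, noise_std, n_days)
        v = rng.normal(0, noise_std, n_days)
        out.append(dc_trajectory(DCSeries(
            id=f"dh{j:04d}", dates=dates, u_dc=u, v_dc=v)))
    return out


def gen_noise_series(
    n_tracks: int = 500,
    n_days: int = 300,
    velocity_noise_std: float = 0.032,
    rng: np.random.Generator | None = None,
    start_date: str = "2005-01-01",
) -> list[DCSeries]:
    """Drifter-like DC-velocity series: pure estimation noise, zero mean."""
    if rng is None:
        rng = np.random.default_rng(0)
    dates = pd.date_range(start_date, periods=n_days, freq="D") + pd.Timedelta(hours=12)
    return [
        dc_trajectory(DCSeries(
            id=f"noi{j:04d}", dates=dates,
            u_dc=rng.normal(0, velocity_noise_std, n_days),
            v_dc=rng.normal(0, velocity_noise_std, n_days),
        ))
        for j in range(n_tracks)
    ]


def gen_seasonal_series(
    n_tracks: int = 60,
    n_days: int = 730,
    amplitude_km: float = 440.0,
    peak_doy: float = 264.0,
    daily_increment_noise_km: float = 1.6,
    rng: np.random.Generator | None = None,
    start_date: str = "2004-06-15",
) -> list[DCSeries]:
    """Meridional DC series with a planted annual positional sine.

    The noise is a daily random walk on y_dc (integrated velocity noise),
    which is what estimation noise looks like after integration.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    out = []
    for j in range(n_tracks):
        dates = (pd.date_range(start_date, periods=n_days, freq="D")
                 + pd.Timedelta(hours=12) + pd.Timedelta(days=int(rng.integers(0, 365))))
        doy = dates.dayofyear.to_numpy(float)
        v = -amplitude_km * 1000.0 * (OMEGA / SECONDS_PER_DAY) * np.sin(
            OMEGA * (doy - peak_doy))
        v = v + rng.normal(0, daily_increment_noise_km * 1000.0 / SECONDS_PER_DAY,
                           n_days)
        s = DCSeries(id=f"sea{j:04d}", dates=dates,
                     u_dc=np.zeros(n_days), v_dc=v)
        out.append(dc_trajectory(s))
    return out


# -- homing-population generator (F_H suite) --------------------------------

@dataclass
class HomingRecord:
    """Lightweight classified-trajectory record for the F_H estimator."""

    id: str
    klass: str  # D_only | H_only | DH
    scl_min: float | None = None
    scl_max: float | None = None
    breakpoint_scl: float | None = None


def gen_homing_population(
    n: int = 300,
    trigger_mean: float = 42.0,
    trigger_sd: float = 4.0,
    rng: np.random.Generator | None = None,
    full_span: bool = False,
    s_min: float = growth_mod.SCL_GRID_MIN,
    s_max: float = growth_mod.SCL_GRID_MAX,
    release_scl_mean: float = 33.0,
    release_scl_sd: float = 5.0,
    duration_days: tuple[int, int] = (400, 1400),
):
    """Classified trajectories implied by a size-threshold homing trigger.

    Each individual homes once its SCL crosses a threshold
    ~ Normal(trigger_mean, trigger_sd) truncated positive.  With
    ``full_span=True`` every individual is observed over the whole SCL grid
    (the estimator then reduces to the empirical threshold CDF); otherwise
    observation windows follow release sizes and tracking durations, like
    real deployments.  Returns ``(records, triggers)``.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    triggers = np.clip(rng.normal(trigger_mean, trigger_sd, n), 1.0, None)
    records = []
    t0 = pd.Timestamp("2005-01-01")
    for j, trig in enumerate(triggers):
        if full_span:
            s0, s1 = s_min, s_max
        else:
            l0 = float(np.clip(rng.normal(release_scl_mean, release_scl_sd),
                               s_min, 50.0))
            days = int(rng.integers(*duration_days))
            p = GrowthParams(l0=l0, t0=t0)
            s0, s1 = l0, float(scl_at(p, t0 + pd.Timedelta(days=days))[0])
        if trig <= s0:
            rec = HomingRecord(id=f"hp{j:04d}", klass="H_only",
                               scl_min=s0, scl_max=s1)
        elif trig < s1:
            rec = HomingRecord(id=f"hp{j:04d}", klass="DH",
                               scl_min=s0, scl_max=s1, breakpoint_scl=float(trig))
        else:
            rec = HomingRecord(id=f"hp{j:04d}", klass="D_only",
                               scl_min=s0, scl_max=s1)
        records.append(rec)
    return records, triggers
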