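"""Synthetic basin generator: fields, drifters, turtles, determinism."""

import numpy as np
import pandas as pd
import pytest

from dcswim import (
    DriftModel, SyntheticConfig, dc_velocity, fit_gamma, gen_drifters,
    gen_fields, gen_turtles, match_fields, velocity_over_ground,
)
from dcswim.synthetic import current_profile, stokes_profile


@pytest.fixture(scope="module")
def cfg():
    return SyntheticConfig(seed=11, n_drifters=30, n_turtles=8,
                           drifter_days=150, turtle_days=420)


@pytest.fixture(scope="module")
def fields(cfg):
    return gen_fields(cfg)


class TestFields:
    def test_nodes_match_analytic_formula(self, cfg, fields):
        lat, lon = 37.5, 150.0
        u, v = fields.sample("current", ["2005-01-01"], [lat], [lon])
        eu, ev = current_profile(cfg, lat, lon)
        assert u[0] == pytest.approx(float(eu), abs=1e-12)
        su, sv = fields.sample("stokes", ["2005-01-01"], [lat], [lon])
        es, _ = stokes_profile(cfg, lat, lon)
        assert su[0] == pytest.approx(float(es), abs=1e-12)

    def test_jet_magnitude_range(self, cfg):
        u_west, _ = current_profile(cfg, 37.5, 120.0)
        u_east, _ = current_profile(cfg, 37.5, 250.0)
        assert u_west == pytest.approx(0.11, abs=1e-12)
        assert u_east == pytest.approx(0.04, abs=1e-12)

    def test_zonal_mean_increases_westward(self, cfg):
        lats = np.linspace(30, 45, 31)
        lons = np.linspace(125, 245, 25)
        means = [np.mean(current_profile(cfg, lats, lo)[0]) for lo in lons]
        assert np.all(np.diff(means) < 0)  # decreasing eastward

    def test_stokes_gyre_is_clockwise(self, cfg):
        u_n, _ = stokes_profile(cfg, 50.0, 185.0)
        u_s, _ = stokes_profile(cfg, 25.0, 185.0)
        _, v_e = stokes_profile(cfg, 37.5, 240.0)
        _, v_w = stokes_profile(cfg, 37.5, 130.0)
        assert u_n > 0 > u_s   # eastward in the north, westward in the south
        assert v_e < 0 < v_w   # southward in the east, northward in the west

    def test_netcdf_roundtrip(self, fields, tmp_path):
        from dcswim import GriddedFieldSet
        fields.to_netcdf(tmp_path / "f.nc")
        back = GriddedFieldSet.from_netcdf(tmp_path / "f.nc")
        assert back.steady
        np.testing.assert_allclose(back.ds["uo"], fields.ds["uo"])


class TestDeterminism:
    def test_same_seed_identical(self, cfg, fields):
        t1, tr1 = gen_drifters(cfg, fields)
        t2, tr2 = gen_drifters(cfg, fields)
        pd.testing.assert_frame_equal(tr1, tr2)
        pd.testing.assert_frame_equal(t1[0].data, t2[0].data)

    def test_different_seed_differs(self, cfg, fields):
        t1, _ = gen_drifters(cfg, fields)
        cfg2 = SyntheticConfig(**{**cfg.to_manifest(), "seed": 99})
        t2, _ = gen_drifters(cfg2, fields)
        assert not np.allclose(t1[0].lat, t2[0].lat[:len(t1[0])])


class TestDrifters:
    def test_pure_current_following_zero_dc(self, fields):
        """gamma_true=0, no noise: DC-velocity vanishes up to the daily
        discretization of the advection (well below a mm/s here)."""
        cfg0 = SyntheticConfig(seed=3, n_drifters=5, drifter_days=100,
                               gamma_drifter=0.0, process_noise_std=0.0,
                               argos_noise_std_m=0.0)
        tracks, _ = gen_drifters(cfg0, fields)
        for t in tracks:
            velocity_over_ground(t)
            match_fields(t, fields)
            s = dc_velocity(t, DriftModel(gamma=0.0))
            assert np.nanmax(np.abs(s.u_dc)) < 1e-3
            assert np.nanmax(np.abs(s.v_dc)) < 1e-3

    def test_process_noise_sqrt_t_dispersal(self, fields):
        """Process noise alone disperses DC-trajectories like a random walk."""
        from dcswim import dc_trajectory, ensemble_stats
        cfg = SyntheticConfig(seed=5, n_drifters=150, drifter_days=200,
                              gamma_drifter=0.88, process_noise_std=0.05,
                              argos_noise_std_m=0.0)
        tracks, _ = gen_drifters(cfg, fields)
        series = []
        for t in tracks:
            velocity_over_ground(t)
            match_fields(t, fields)
            series.append(dc_trajectory(dc_velocity(t, DriftModel(gamma=0.88))))
        out = ensemble_stats(series, min_n=20)
        s50 = out["std_x"].iloc[50]
        s180 = out["std_x"].iloc[180]
        assert s180 / s50 == pytest.approx(np.sqrt(180 / 50), rel=0.25)

    def test_gamma_recovery_small_run(self, cfg, fields):
        tracks, _ = gen_drifters(cfg, fields)
        for t in tracks:
            velocity_over_ground(t)
            match_fields(t, fields)
        m = fit_gamma(tracks, fit_domain="buoys")
        assert m.gamma == pytest.approx(0.88, abs=5 * m.gamma_stderr)


class TestTurtles:
    def test_truth_table_complete(self, cfg, fields):
        tracks, truth, individuals = gen_turtles(cfg, fields)
        assert {"vs_u", "vs_v", "scl", "gamma_true"} <= set(truth.columns)
        assert len(individuals) == cfg.n_turtles
        assert (individuals["trigger_scl"] > 0).all()

    def test_null_turtles_look_like_drifters(self, fields):
        """Swim disabled: turtle DC-velocities are statistically
        indistinguishable from drifter DC-velocities (two-sample test)."""
        from scipy.stats import ks_2samp
        base = dict(seed=7, drifter_days=200, turtle_days=200,
                    process_noise_std=0.0, foraging_rw_std=0.0)
        cfg_d = SyntheticConfig(n_drifters=30, gamma_drifter=0.28, **base)
        cfg_t = SyntheticConfig(n_turtles=30, **base)
        dr, _ = gen_drifters(cfg_d, fields)
        tt, _, _ = gen_turtles(cfg_t, fields, seasonal=False, homing=False,
                               foraging=False)
        def pooled(tracks):
            out = []
            for t in tracks:
                velocity_over_ground(t)
                match_fields(t, fields)
                s = dc_velocity(t, DriftModel(gamma=0.28))
                out.append(s.u_dc[np.isfinite(s.u_dc)])
            return np.concatenate(out)
        u_d, u_t = pooled(dr), pooled(tt)
        assert ks_2samp(u_d, u_t).pvalue > 0.01

    def test_zero_noise_identity_full_pipeline(self, fields):
        """With all noise off and homing from release, the recovered
        DC-velocity equals the planted swimming velocity to < 1e-3 m/s."""
        cfg = SyntheticConfig(seed=2, n_turtles=3, turtle_days=400,
                              foraging_rw_std=0.0, argos_noise_std_m=0.0,
                              process_noise_std=0.0,
                              trigger_scl_mean=1.0, trigger_scl_sd=0.0)
        tracks, truth, _ = gen_turtles(cfg, fields)
        worst = 0.0
        for t in tracks:
            velocity_over_ground(t)
            match_fields(t, fields)
            s = dc_velocity(t, DriftModel(gamma=cfg.gamma_turtle))
            tr = truth[truth["id"] == t.id]
            err_u = np.abs(s.u_dc[1:-1] - tr["vs_u"].to_numpy()[1:-1])
            err_v = np.abs(s.v_dc[1:-1] - tr["vs_v"].to_numpy()[1:-1])
            worst = max(worst, np.nanmax(err_u), np.nanmax(err_v))
        assert worst < 1e-3

    def test_exit_truncation(self, fields):
        cfg = SyntheticConfig(seed=4, n_turtles=6, turtle_days=3000,
                              trigger_scl_mean=1.0, trigger_scl_sd=0.0,
                              release_box_turtles=((30.0, 34.0), (128.0, 132.0)))
        tracks, _, _ = gen_turtles(cfg, fields)
        assert all(len(t) < 3000 for t in tracks)  # homing west out of the basin
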