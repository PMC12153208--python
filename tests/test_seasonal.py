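"""Annual sine fitting, circular phase statistics, binned and annual-mean views."""

import numpy as np
import pandas as pd
import pytest

from dcswim import (
    annual_mean_meridional_trajectory, binned_meridional_means,
    circular_mean_phase, doy_to_date, fit_annual_sine, migration_distance_km,
    seasonal_vectors,
)
from dcswim.seasonal import OMEGA, YEAR_DAYS
from dcswim.kinematics import dc_trajectory
from tests_util import make_series


def planted_sine_series(amplitude_km=440.0, peak_doy=264.0, n_days=730,
                        start="2004-06-15", trend=0.0, noise_km=0.0, rng=None,
                        tid="ps"):
    """DC series whose y_dc is an exact annual sine peaking on peak_doy."""
    dates = pd.date_range(start, periods=n_days, freq="D") + pd.Timedelta(hours=12)
    doy = dates.dayofyear.to_numpy(float)
    v = -amplitude_km * 1000.0 * (OMEGA / 86400.0) * np.sin(OMEGA * (doy - peak_doy))
    s = make_series(np.zeros(n_days), v, start=start, tid=tid)
    s = dc_trajectory(s)
    if trend:
        s.y_dc = s.y_dc + trend * np.arange(n_days)
    if noise_km and rng is not None:
        s.y_dc = s.y_dc + np.cumsum(rng.normal(0, noise_km, n_days))
    return s


class TestFitAnnualSine:
    @pytest.mark.parametrize("peak_doy", [30.0, 150.0, 264.0, 340.0])
    def test_noiseless_recovery_any_phase(self, peak_doy):
        s = planted_sine_series(peak_doy=peak_doy)
        f = fit_annual_sine(s)
        # daily integration + calendar quantization cost ~a day of phase
        assert f.amplitude_km == pytest.approx(440.0, rel=5e-3)
        assert abs(f.peak_doy - peak_doy) < 2.0
        assert f.eligible

    @pytest.mark.parametrize("peak_doy", [30.0, 264.0])
    def test_exact_recovery_on_direct_sine(self, peak_doy):
        """y_dc built directly as offset + trend + annual sine is recovered
        to near machine precision (the fit is linear algebra)."""
        s = dc_trajectory(make_series(np.zeros(700), np.zeros(700),
                                      start="2005-01-10"))
        t = np.arange(700.0)
        t_peak = (pd.Timestamp("2005-01-01") + pd.Timedelta(days=peak_doy - 1)
                  - s.dates[0].normalize()) / pd.Timedelta(days=1)
        s.y_dc = 12.0 + 0.3 * t + 440.0 * np.cos(OMEGA * (t - t_peak))
        f = fit_annual_sine(s)
        assert f.amplitude_km == pytest.approx(440.0, rel=1e-9)
        assert abs(f.peak_doy - (peak_doy + 0.5)) < 1e-6  # noon-stamped dates

    def test_zero_series_zero_amplitude(self):
        s = dc_trajectory(make_series(np.zeros(400), np.zeros(400)))
        f = fit_annual_sine(s)
        assert f.amplitude_km == pytest.approx(0.0, abs=1e-9)

    def test_trend_absorbed(self):
        s = planted_sine_series(trend=1.5)
        f = fit_annual_sine(s, trend=True)
        assert f.amplitude_km == pytest.approx(440.0, rel=5e-3)
        assert f.trend_km_per_day == pytest.approx(1.5, abs=0.05)

    def test_short_series_rejected(self):
        s = dc_trajectory(make_series(np.zeros(20), np.zeros(20)))
        with pytest.raises(ValueError, match="30"):
            fit_annual_sine(s)

    def test_eligibility_span(self):
        s = planted_sine_series(n_days=200)
        assert not fit_annual_sine(s).eligible

    def test_amplitude_bias_under_white_noise(self, rng):
        """White observation noise does not bias the amplitude appreciably."""
        amps = []
        for k in range(60):
            s = planted_sine_series(n_days=730, tid=f"n{k}")
            s.y_dc = s.y_dc + rng.normal(0, 30.0, 730)
            amps.append(fit_annual_sine(s).amplitude_km)
        assert np.mean(amps) == pytest.approx(440.0, abs=5.0)


class TestCircularMeanPhase:
    def test_identical_phases(self):
        doy, R = circular_mean_phase([264.0] * 10)
        assert doy == pytest.approx(264.0, abs=1e-9)
        assert R == pytest.approx(1.0)

    def test_wraparound_new_year(self):
        doy, _ = circular_mean_phase([365.0, 2.0])
        assert doy < 5 or doy > 360
        assert doy_to_date(doy + 1).month in (12, 1)

    def test_uniform_phases_undefined(self):
        with pytest.raises(ValueError, match="undefined|balanced"):
            circular_mean_phase(np.linspace(0, YEAR_DAYS, 73, endpoint=False))

    def test_rotation_equivariance(self, rng):
        base = rng.uniform(0, 300, 40)
        m0, _ = circular_mean_phase(base)
        m1, _ = circular_mean_phase((base + 50) % YEAR_DAYS)
        assert (m1 - m0) % YEAR_DAYS == pytest.approx(50.0, abs=1e-6)


class TestBinnedMeans:
    def _table(self, doys, lats, v):
        return pd.DataFrame({
            "date": pd.Timestamp("2005-01-01"), "doy": doys, "lat": lats, "v_dc": v,
        })

    def test_constant_velocity_everywhere(self):
        n = 6000
        t = self._table(np.tile(np.arange(1, 61), 100),
                        np.repeat(np.linspace(30, 35, 100), 60), np.full(n, 0.06))
        out = binned_meridional_means(t)
        shown = out[np.isfinite(out["mean_v_dc"])]
        assert len(shown) > 0
        np.testing.assert_allclose(shown["mean_v_dc"], 0.06)

    def test_count_mask_boundary(self):
        t50 = self._table(np.full(50, 10), np.full(50, 30.5), np.full(50, 0.1))
        t51 = self._table(np.full(51, 10), np.full(51, 30.5), np.full(51, 0.1))
        assert np.isnan(binned_meridional_means(t50)["mean_v_dc"].iloc[0])
        assert binned_meridional_means(t51)["mean_v_dc"].iloc[0] == pytest.approx(0.1)

    def test_seasonal_sign_flip_week(self):
        """Southward swimming after the fall-equinox peak flips the binned
        means' sign between weeks 37 and 38 at every populated latitude."""
        doys = np.tile(np.arange(1, 366), 200)
        lats = np.repeat(np.linspace(28.005, 41.995, 200), 365)
        v = -0.06 * np.sin(OMEGA * (doys - 264.0))
        out = binned_meridional_means(self._table(doys, lats, v))
        for lat_bin, sub in out.groupby("lat_bin"):
            sub = sub.set_index("week")["mean_v_dc"]
            # descending zero crossing sits inside week 38 (doys 260-266)
            assert sub.loc[37] > 0 > sub.loc[39]
            assert abs(sub.loc[38]) < 0.01


class TestAnnualMeanTrajectory:
    def test_constant_velocity_linear(self):
        t = pd.DataFrame({"doy": np.tile(np.arange(1, 366), 3),
                          "v_dc": 0.05, "date": pd.Timestamp("2005-01-01")})
        out = annual_mean_meridional_trajectory(t)
        np.testing.assert_allclose(np.diff(out["y_km"]), 0.05 * 86.4, atol=1e-9)
        assert migration_distance_km(out) == pytest.approx(0.05 * 86.4 * 365, rel=1e-6)

    def test_planted_sine_closed_form(self):
        """Velocity amplitude a integrates to migration distance 2 a / omega."""
        a = 0.0876
        doys = np.tile(np.arange(1, 366), 5)
        v = -a * np.sin(OMEGA * (doys - 264.0))
        t = pd.DataFrame({"doy": doys, "v_dc": v, "date": pd.Timestamp("2005-01-01")})
        out = annual_mean_meridional_trajectory(t)
        expect = 2 * a / (OMEGA / 86400.0) / 1000.0  # km
        assert migration_distance_km(out) == pytest.approx(expect, rel=0.005)

    def test_gap_fill(self):
        doys = np.arange(1, 366)
        v = np.full(365, 0.05)
        keep = (doys < 100) | (doys > 120)
        t = pd.DataFrame({"doy": doys[keep], "v_dc": v[keep],
                          "date": pd.Timestamp("2005-01-01")})
        out = annual_mean_meridional_trajectory(t)
        assert np.isfinite(out["mean_v_dc"]).all()
        np.testing.assert_allclose(out["mean_v_dc"], 0.05, atol=1e-12)


class TestSeasonalVectors:
    def _table(self, dates, u, v):
        return pd.DataFrame({"date": dates, "u_dc": u, "v_dc": v,
                             "doy": pd.DatetimeIndex(dates).dayofyear, "lat": 35.0})

    def test_zero_input(self):
        dates = pd.date_range("2005-01-01", periods=365, freq="D")
        out = seasonal_vectors(self._table(dates, np.zeros(365), np.zeros(365)))
        assert set(out["season"]) == {"DJF", "MAM", "JJA", "SON"}
        np.testing.assert_allclose(out["mean_u_dc"], 0.0)

    def test_homing_plus_seasonal_structure(self):
        dates = pd.date_range("2005-01-01", periods=365, freq="D")
        doy = dates.dayofyear.to_numpy(float)
        u = np.full(365, -0.10)
        v = -0.06 * np.sin(OMEGA * (doy - 264.0))
        out = seasonal_vectors(self._table(dates, u, v)).set_index("season")
        assert (out["mean_u_dc"] < -0.05).all()  # westward in all seasons
        assert out.loc["JJA", "mean_v_dc"] > 0 > out.loc["DJF", "mean_v_dc"]
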