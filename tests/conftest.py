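import numpy as np
import pandas as pd
import pytest
import xarray as xr

from dcswim import DailyTrack, GriddedFieldSet


def make_track(lat, lon, start="2005-03-01", tid="t0", **kw):
    """Track from raw position arrays, noon-stamped daily."""
    n = len(lat)
    idx = pd.date_range(start, periods=n, freq="D") + pd.Timedelta(hours=12)
    data = pd.DataFrame({"lat": np.asarray(lat, float),
                         "lon": np.asarray(lon, float)}, index=idx)
    return DailyTrack(id=tid, data=data, **kw)


def make_fields(lat, lon, uo, vo, vsdx, vsdy, time=None):
    coords = {"lat": lat, "lon": lon}
    dims = ("lat", "lon")
    if time is not None:
        coords["time"] = time
        dims = ("time", "lat", "lon")
    ds = xr.Dataset(
        {k: (dims, v) for k, v in
         [("uo", uo), ("vo", vo), ("vsdx", vsdx), ("vsdy", vsdy)]},
        coords=coords,
    )
    return GriddedFieldSet(ds=ds, steady=time is None)


@pytest.fixture
def constant_fields():
    """Steady uniform fields: current (0.2, 0), Stokes (0.05, 0.05)."""
    lat = np.arange(20.0, 51.0, 1.0)
    lon = np.arange(140.0, 201.0, 1.0)
    shp = (len(lat), len(lon))
    return make_fields(lat, lon,
                       np.full(shp, 0.2), np.zeros(shp),
                       np.full(shp, 0.05), np.full(shp, 0.05))


@pytest.fixture
def linear_fields():
    """Steady fields linear in lat and lon (bilinear sampling is exact)."""
    lat = np.arange(20.0, 51.0, 1.0)
    lon = np.arange(140.0, 201.0, 1.0)
    LAT, LON = np.meshgrid(lat, lon, indexing="ij")
    return make_fields(lat, lon,
                       0.01 * (LAT - 35.0), 0.002 * (LON - 170.0),
                       0.001 * (LON - 170.0), -0.002 * (LAT - 35.0))


@pytest.fixture
def rng():
    return np.random.default_rng(20250921)
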