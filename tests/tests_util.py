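import numpy as np
import pandas as pd

from dcswim import DCSeries


def make_series(u, v, start="2005-01-01", tid="s0", lat=None, scl=None):
    n = len(u)
    dates = pd.date_range(start, periods=n, freq="D") + pd.Timedelta(hours=12)
    return DCSeries(
        id=tid, dates=dates,
        u_dc=np.asarray(u, float), v_dc=np.asarray(v, float),
        lat=None if lat is None else np.asarray(lat, float),
        scl=None if scl is None else np.asarray(scl, float),
    )
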