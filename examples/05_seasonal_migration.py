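"""Quantify seasonal north-south migration with annual sine fits.

Plants meridional DC-trajectories oscillating with a 440-km amplitude and
a September-21 (fall equinox) peak under random-walk noise, fits the fixed
365.25-day harmonic per track, and summarizes the population phase with a
circular mean.
"""

import numpy as np

from dcswim import (
    circular_mean_phase, doy_to_date, fit_annual_sine, gen_seasonal_series,
)

rng = np.random.default_rng(11)
series = gen_seasonal_series(n_tracks=40, n_days=730, amplitude_km=440.0,
                             peak_doy=264.0, daily_increment_noise_km=2.2,
                             rng=rng)

fits = [fit_annual_sine(s) for s in series]
eligible = [f for f in fits if f.eligible]
amp = np.mean([f.amplitude_km for f in eligible])
doy, R = circular_mean_phase(eligible)

print(f"{len(eligible)} tracks longer than a year")
print(f"mean amplitude      = {amp:.0f} km "
      f"(migration distance {2*amp:.0f} km = twice the amplitude)")
print(f"circular mean peak  = day {doy:.1f} ~ {doy_to_date(doy).strftime('%b %d')} "
      f"(resultant length {R:.2f})")
# the planted 440-km amplitude and fall-equinox phase come back within a
# few km / days; R near 1 means the population is tightly phase-locked
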