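# dcswim

**Drift-corrected swimming velocities from satellite telemetry.**

Where does the ocean stop carrying an animal and the animal start swimming?
For a tracked marine animal, the velocity over ground mixes both:

    V_g = V_s + V_d,        V_d = V_co + γ·V_sto

with `V_co` the surface Eulerian current, `V_sto` the surface Stokes drift,
and γ a leeway coefficient absorbing wave- and wind-induced drift. `dcswim`
estimates the swimming velocity as the **drift-corrected (DC) velocity**

    V_DC = V_g − (V_co + γ·V_sto)

and integrates it into a **DC-trajectory** — cumulative swimming
displacement in a local plane. Slow persistent swimming (1 cm/s ≈ 315 km/yr)
that is invisible in daily fixes becomes a large, measurable signal.

The package is aimed at movement ecologists working with daily-regularized
Argos tracks (e.g. juvenile sea turtles) and gridded ocean/wave reanalysis
fields, and at anyone needing the downstream behavioral analyses:

- **tracks** — daily-track I/O, midnight interpolation, daily-mean
  velocity over ground in a local metric;
- **fields** — gridded current/Stokes containers (NetCDF, CF-style),
  daily averaging, masked bilinear sampling, track matching, 5°×5° box
  statistics;
- **leeway** — γ estimation by stacked 2-D least squares on undrogued
  drifters or animal tracks (reference values: 0.88 for surface buoys,
  0.28 for juvenile loggerheads);
- **kinematics** — DC-velocities, DC-trajectories, ensemble statistics,
  drift-noise maps;
- **segmentation** — two-segment least-squares breakpoints on the zonal
  DC-trajectory and the drifting/homing/unreliable (D/H/U) taxonomy
  (thresholds −6.5 cm/s, 90 days, 0.25 m/s);
- **seasonal** — fixed-period annual sine fits of meridional
  DC-trajectories, circular mean phase, latitude×week binned means,
  annual mean migration distance, season-mean vectors;
- **growth** — daily von Bertalanffy size imputation
  (L∞ = 100.06 cm, K = 0.066/yr) and the size-conditional homing
  probability F_H(SCL), plus Rayleigh breakpoint seasonality;
- **synthetic** — a seedable North Pacific-like basin (eastward jet,
  clockwise Stokes gyre, programmed drifters and turtles with truth
  tables) so the whole pipeline is testable without any data download.

## Worked example

```python
import numpy as np
from dcswim import (SyntheticConfig, gen_fields, gen_drifters,
                    velocity_over_ground, match_fields, fit_gamma)

cfg = SyntheticConfig(seed=7, n_drifters=120, drifter_days=250)
fields = gen_fields(cfg)                 # steady jet + Stokes gyre
tracks, truth = gen_drifters(cfg, fields)  # V_d = V_co + 0.88 V_sto + noise

for t in tracks:
    velocity_over_ground(t)              # daily-mean V_g from midnights
    match_fields(t, fields)              # bilinear sampling at noon fixes

model = fit_gamma(tracks, fit_domain="buoys")
print(f"gamma = {model.gamma:.3f} +- {model.gamma_stderr:.3f}")
```

prints

```
gamma = 0.871 +- 0.006
```

the planted leeway coefficient 0.88 recovered within two standard errors
from 29,760 noisy drifter-days. The `examples/` directory has one short
script per capability (basin simulation, leeway regression,
DC-trajectories, segmentation, seasonal migration, homing probability),
each printing the numbers it computes and what they mean.

A thin CLI mirrors the pipeline for shell use:

```bash
dcswim simulate --out run --seed 3
dcswim match --tracks run/drifters.csv --fields run/fields.nc --out run/matched.csv
dcswim fit-leeway --tracks run/matched.csv --out run/model.json
dcswim dc --tracks run/matched.csv --gamma 0.28 --out run/dc.csv
dcswim segment --tracks run/dc.csv --out run/classification.csv
```

Every subcommand writes a manifest (resolved options + input hashes) so
runs reproduce byte-for-byte.

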