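"""At what size does homing start?  F_H(SCL) from classified trajectories.

Plants a population whose homing trigger is a per-individual size threshold
~ Normal(42, 4) cm, classifies each track (drifting-only / homing-only /
drifting-then-homing with the size at the breakpoint), and estimates the
probability that homing has begun before each size on a 1-cm grid.
"""

import numpy as np
from scipy.stats import norm

from dcswim import estimate_f_h, gen_homing_population

rng = np.random.default_rng(99)
records, triggers = gen_homing_population(300, trigger_mean=42.0,
                                          trigger_sd=4.0, rng=rng,
                                          full_span=True)
cdf = estimate_f_h(records)

print("SCL   n_D  n_H   F_H   planted CDF")
for s in (30, 38, 42, 46, 50, 60):
    i = int(np.flatnonzero(cdf.scl_grid == s)[0])
    print(f"{s:3d}  {cdf.n_d[i]:4d} {cdf.n_h[i]:4d}  {cdf.f_h[i]:.3f}  "
          f"{norm.cdf((s - 42) / 4):.3f}")
# F_H tracks the planted threshold distribution: ~50% of individuals have
# initiated homing by 42 cm and >95% by 50 cm under this trigger model
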