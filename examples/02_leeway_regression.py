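"""Estimate the leeway coefficient gamma from synthetic undrogued drifters.

Simulates drifters whose drift is V_co + 0.88 * V_sto + noise, runs the
velocity-over-ground / field-matching pipeline on the noisy reported
positions, and fits gamma by the stacked 2-D regression of the observed
leeway (V_g - V_co) on the Stokes drift.
"""

from dcswim import (
    SyntheticConfig, fit_gamma, gen_drifters, gen_fields, match_fields,
    velocity_over_ground,
)

cfg = SyntheticConfig(seed=7, n_drifters=120, drifter_days=250)
fields = gen_fields(cfg)
tracks, _ = gen_drifters(cfg, fields)

for t in tracks:
    velocity_over_ground(t)   # daily-mean velocity from midnight positions
    match_fields(t, fields)   # bilinear sampling at each noon fix

model = fit_gamma(tracks, fit_domain="buoys")
print(f"planted gamma = {cfg.gamma_drifter}")
print(f"fitted  gamma = {model.gamma:.3f} +- {model.gamma_stderr:.3f} "
      f"({model.n_obs} drifter-days)")
print(f"intercepts (model-bias diagnostic): "
      f"mu = ({model.mu_u*100:.2f}, {model.mu_v*100:.2f}) cm/s")
# gamma lands on the planted 0.88 within a couple of standard errors;
# near-zero intercepts mean the drift model carries no systematic bias
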