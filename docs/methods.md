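# Methods

## The problem

A satellite-tracked marine animal's velocity over ground is the sum of its
own swimming velocity and a drift velocity imparted by the environment:

    V_g = V_s + V_d

For surface-dwelling animals (here, pelagic juvenile loggerhead-like
swimmers) and undrogued surface buoys, the drift has two parts: the
Eulerian current of the uppermost ocean layer, and a wave/wind-induced
*leeway*. `dcswim` estimates the swimming velocity by subtracting a modeled
drift from the observed velocity over ground,

    V_DC = V_g − (V_co + γ·V_sto),

the **drift-corrected (DC) velocity**, and integrates it in a local plane
into a **DC-trajectory** — cumulative swimming displacement with origin
(0, 0) at release. Persistent swimming as slow as 1 cm/s, invisible in any
single daily velocity, accumulates to >300 km/yr in the DC-trajectory.

## Velocity over ground

Tracks are daily positions at 12:00 UTC (state-space filtering of raw Argos
fixes is assumed upstream). Gridded current and Stokes fields are daily
means over 0:00–24:00 UTC, so velocities over ground are computed over the
same window: midnight positions are linearly interpolated between adjacent
noon fixes, and the displacement between consecutive midnights divided by
86,400 s is stored on the intervening day. This is algebraically identical
to a centered difference on the noon fixes, `(X(d+1) − X(d−1)) / 2Δt`, so
no second variant is needed.

Degrees are converted to meters in a local equirectangular frame
(spherical Earth, R = 6,371,000 m, zonal scale cos(latitude) at the
segment-mean latitude). The metric error on a daily displacement is
<0.2 %, far below position noise. Longitudes are unwrapped per track and
field longitudes are stored in [0, 360), because the domain (120°E–110°W)
straddles the antimeridian. Any missing calendar day splits a track into
independent blocks; nothing is gap-filled at the position level.

**Estimation noise.** With independent 1-km per-component errors on the two
positions bounding a day, the velocity error std is √2·σ/Δt ≈ 1.6 cm/s.
Because our midnight positions are *averages* of adjacent noon fixes, the
noise on the midnight-differenced velocity from noisy noon fixes is
σ/(√2·Δt) ≈ 0.8 cm/s per component (with mild anti-correlation two days
apart). Both closed forms are verified by Monte-Carlo in the test suite.
Either way the daily noise is of order 1–2 cm/s — the reason segment-mean
DC-velocities, not daily values, carry the behavioral signal.

## Drift model and leeway coefficient

The drift is modeled as

    V_d = V_co + γ·V_sto

with `V_co` the 0–1 m Eulerian current and `V_sto` the surface Stokes
drift; γ is a scalar leeway coefficient folding in windage (strongly
correlated with the Stokes drift). γ is estimated by ordinary least squares
on the observed leeway `V_g − V_co` against `V_sto`, stacking the zonal and
meridional equations so one γ is shared while each component keeps its own
intercept μ. The intercepts are diagnostics of systematic model bias and
are **not** added when predicting drift. Reference magnitudes: γ ≈ 0.88 for
undrogued surface buoys (floating in the top ~30 cm) and γ ≈ 0.28 for
juvenile loggerheads (diving mostly within 1–15 m, where the Stokes drift
decays). Implementation: `numpy.linalg.lstsq` with closed-form OLS standard
errors; a near-constant Stokes regressor is rejected as degenerate, and a
`min_days` floor (default 100 pooled days) guards against meaningless fits.

For buoys `V_s = 0`, so the regression residual is pure estimation noise.
For animals, the swimming velocity enters the residual; γ stays unbiased
exactly insofar as swimming is uncorrelated with the *along-track* Stokes
drift. A caveat found with the synthetic basin: deterministic behavioral
programs couple to the fields through the animal's own position (e.g.
homing days occur late in a track, when the animal has been carried to
latitudes with different Stokes drift). With tens of individuals sharing a
seasonal phase, this correlation decays only like 1/√(n_tracks) and can
shift γ̂ by ±0.1 under the default synthetic conditions — steady fields
whose Stokes variance is far below real synoptic wave variability. The
validation study for turtle-γ therefore tests the stated identifiability
condition (swimming independent of `V_sto`: an isotropic foraging walk);
real-data fits lean on hundreds of individuals, multi-year records and
weather-driven Stokes variance.

## Matching tracks to fields

Sub-daily fields are averaged to daily means first. Both fields are sampled
at each day's 12:00 UTC position by bilinear interpolation over the four
surrounding nodes; when 1–3 nodes are masked (land), weights are
renormalized over the valid nodes (avoiding spurious zeros along coasts,
where estimation noise is largest anyway); all four masked, or a day
missing from the time axis, yields a missing value, never zero. Points
outside the grid hull are an error when sampled directly and are left
unmatched (with a logged count) when matching whole tracks.

## Segmentation and the D/H/U taxonomy

Behavior is read off the zonal DC-velocity. Every trajectory is split into
exactly two segments at the breakpoint minimizing the within-segment sum of
squares of daily `u_dc` (two-regime piecewise-constant-mean model,
equivalently a continuous two-piece linear fit to `x_dc(t)`); ties resolve
to the earliest index, missing days are excluded from the sums. The search
is O(n) by prefix sums and is property-tested against an exhaustive O(n²)
oracle. Each segment is classified:

- **U** (unreliable): duration < 90 days, or std of `u_dc` > 0.25 m/s —
  checked first, so a short strongly-westward segment is still U;
- **H** (homing): mean `u_dc` < −6.5 cm/s;
- **D** (drifting): otherwise.

Segment durations are calendar days inclusive; segment std is the
population std (a noise magnitude, not a sampling estimate). The segment
pair maps onto five trajectory classes: U (both U or track < 90 d), D-only
({D,D} or one D + one U), H-only (likewise with H), DH (D then H, recording
the breakpoint date and the size S_b at the breakpoint), HD (H then D).
At the −6.5 cm/s threshold itself a segment is D: the threshold is a strict
lower bound for homing. Noise at the levels implied by the generator
defaults produces essentially no false H segments (validated at the
0.05 m/s process-noise bound).

## Seasonal migration

The meridional DC-trajectory is fit per track with a fixed-period annual
harmonic `y_dc(t) = c + b·t + A·sin(ωt + θ)`, ω = 2π/365.25 d⁻¹, linear in
(c, b, A·cosθ, A·sinθ). The trend `b` absorbs non-seasonal meridional
drift (flag `trend=False` available for sensitivity checks). The phase is
reported as the fractional day-of-year of the sine maximum; amplitudes are
nonnegative by construction. Tracks spanning more than a year are flagged
`eligible` (amplitude/phase well constrained); ill-conditioned designs are
flagged unreliable. Population phase is the circular mean of peak
days-of-year mapped to the unit circle; it is undefined (error) when the
resultant length vanishes. Convention note: daily integration and
noon-stamped dates cost ~half a day of phase, and the day-of-year of the
principal peak can differ by one across leap years; phase comparisons in
the tests allow ~2 days for these conventions.

Discrete views: mean meridional DC-velocity in [1° latitude × 7 day]
boxes, masked where a cell has ≤50 samples; day-of-year mean meridional
velocities (each segment-day weighted equally) integrated from January 1
into an annual mean trajectory whose peak-to-trough excursion is the
migration distance (for a planted velocity sine of amplitude a this is
2a/ω, verified in closed form); and season-mean DC-velocity vectors over
meteorological seasons (DJF/MAM/JJA/SON).

## Size and the homing probability

Sizes (straight carapace length, SCL, cm) are imputed daily from the
release measurement with a von Bertalanffy curve
`L(t) = L∞ − (L∞ − L₀)·e^(−K(t−t₀))`, L∞ = 100.06 cm, K = 0.066/yr
(literature values for North Pacific loggerheads; years of 365.25 days
since tracks span leap years). Growth parameters are fixed, not fitted.

The probability that homing has begun before size s,
`F_H(s) = n_H(s) / (n_H(s) + n_D(s))`, is estimated on a 1-cm grid from
25 to 85 cm under a single-transition assumption (drifting switches to
homing at most once; the rare HD trajectories are excluded, U discarded):
a drifting-only track with observed size range [S₀, S₁] counts as drifting
at every s ≤ S₁ (also below S₀ — it cannot have homed earlier); a
homing-only track counts as homing at every s ≥ S₀; a DH track counts as
drifting at s ≤ S_b and homing at s ≥ S_b, both closed at S_b (the
boundary convention affects at most one count). Grid points with an empty
denominator are undefined, never zero. When every track spans the full
grid, the estimator reduces to the empirical CDF of the per-individual
trigger sizes — the basis of the recovery study.

Breakpoint seasonality uses a Rayleigh test on breakpoint days-of-year
mapped to angles 2π·doy/365.25: Z = n·R̄², p ≈ e^(−Z)·[1 + (2Z − Z²)/(4n)]
clipped to [0, 1]; refused below n = 5 where the approximation fails. The
test's type-I error is calibrated by simulation in the validation suite.

## The synthetic basin

The generator provides everything the estimators consume, with ground
truth, for a basin spanning 20–55°N, 120°E–110°W on a 0.5° grid:

- **Current**: steady eastward zonal jet between 30–45°N (flat-topped
  quartic profile in latitude), 4 cm/s at the eastern edge strengthening
  to 11 cm/s at the western boundary; zero meridional component. Steady
  fields represent the climatological circulation; dated daily axes and
  sub-daily averaging are fully supported for real inputs.
- **Stokes drift**: steady clockwise gyre, linear in latitude and
  longitude, 5 cm/s maximum. Linearity makes bilinear sampling exact,
  keeping the zero-noise identity clean.
- **Drifters**: daily Euler advection `X(t+1) = X(t) + (V_co + γ·V_sto +
  η)·Δt` with γ = 0.88, isotropic process noise η (default std 0.03 m/s,
  standing in for unresolved sub-grid variability of the smooth analytic
  fields), and Argos-like reported-position noise (1 km per component).
  Daily Euler stepping (not RK4) deliberately matches the daily-mean data
  cadence and the estimator's own discretization. Tracks truncate when a
  particle exits the basin.
- **Turtles**: as drifters with γ = 0.28 plus a swimming program — an
  annual meridional sinusoid specified in velocity space with the
  *positional* peak on the configured date (default Sept 21; velocity
  leads position by a quarter period; default velocity amplitude
  0.0876 m/s ↔ 440 km positional amplitude); an isotropic foraging walk
  (0.02 m/s); and sustained westward homing switched on when the imputed
  SCL crosses a per-individual threshold ~ Normal(42, 4) cm, with speed
  scaling linearly from 0.09 m/s at 35 cm to 0.15 m/s at 55+ cm.
  Releases are staggered in monthly cohorts over a year (mirroring real
  multi-season deployments; a single shared release date would alias the
  shared seasonal program onto the along-track Stokes drift).
- Truth tables record noise-free positions, planted swimming velocities,
  daily sizes and trigger dates; identical config + seed reproduces
  outputs bit-for-bit.

What the generator does **not** emulate: mesoscale eddies and their
position errors (the dominant real noise near the Kuroshio, where
DC-velocity stds reach ~0.5 m/s — the random-walk scaling of that spread
is tested, its dynamics are not), temporal variability of the wave field,
temperature-dependent behavior or mortality, and real Argos error
heavy-tailedness. Passing the recovery suites therefore demonstrates
estimator correctness under the stated noise model, not performance on any
particular real data set.

## Validation studies and problem sizes

`dcswim.validation` re-runs each study end-to-end; tests assert them at
fixed tolerances and `scripts/acceptance.py` reports them for any seed:

1. **Leeway recovery** — 200 drifters × 300 days, planted γ = 0.88,
   full pipeline; |γ̂ − 0.88| < 0.02.
2. **Zero-noise identity** — all noise off, homing from release: recovered
   DC-velocity equals the planted swimming velocity to <10⁻³ m/s daily
   (residual: half-day discretization and field-curvature sampling).
3. **Breakpoint recovery** — 100 planted DH series, switch at day 250,
   noise σ = 0.15 m/s: median |error| ≤ 5 days, ≥95 % classified DH.
4. **Seasonal recovery** — 60 series × 730 days, planted 440 km /
   Sept 21, random-walk increment noise 2.2 km/day (the level implied by
   the generator defaults): mean amplitude within 5 %, circular mean peak
   within 3 days.
5. **F_H recovery** — 300 full-span tracks, triggers ~ Normal(42, 4):
   sup-norm distance to the planted CDF ≤ 0.1.
6. **False-homing guard** — 500 noise-only series at the 0.05 m/s
   process-noise bound: <1 % of segments classified H.
7. **Rayleigh calibration** — 500 replicates of 30 uniform dates:
   empirical type-I error ≈ 1 % at α = 0.01.

These sizes keep every study seconds-scale while leaving comfortable
statistical margins; all scale up linearly via function arguments.

## Numerical conventions

Breakpoint ties break to the earliest index with a relative 10⁻¹²
tolerance; segment and box-statistic stds are population stds while
ensemble stds across tracks use ddof = 1; DC-trajectories store the
position at the *start* of each day (x_dc[0] = 0) with `final_x`/`final_y`
exposing the post-last-increment displacement; missing DC days contribute
zero displacement and are counted, never interpolated; empty
days-of-year in the annual mean trajectory are linearly gap-filled with a
logged warning; F_H is NaN where undefined. Fields are written as
NetCDF3 via xarray's scipy engine with CF-style axes (lat/lon/time) and
variable names `uo`/`vo`/`vsdx`/`vsdy`, so reanalysis extractions in the
same layout are drop-in replacements.
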