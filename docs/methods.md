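# Methods

## Scope and architecture

`growcab` reproduces the software layer of a networked smart growth cabinet —
recipe scheduling, adaptive predictive temperature control, heartbeat
telemetry, actuator calibration, ToF height phenotyping, and tracking metrics —
against a simulated thermal plant instead of hardware. Six modules mirror that
decomposition: `recipes`, `cabinet`, `mpc`, `heartbeat`, `phenotype`,
`metrics`, plus `config` (plain-text `key = value` files) and `cli` (a click
group wrapping the library). Nothing here talks to real sensors, MQTT brokers
or databases; the system heartbeat's connectivity check is a no-op log entry.

## Climate recipes

A recipe is a strictly time-ordered CSV schedule
(`offset_s,temp_c,rh_pct,light_v,irrigation_s`) with a minimum row spacing of
30 s and a mandatory first row at offset 0, so the controller always has a
defined target. Semantics are zero-order hold on left-closed intervals — the
row at or before `t` applies, and the last row holds indefinitely. Hold was
chosen over interpolation because a cabinet checks its schedule and "changes if
required"; linear interpolation is available only when converting a coarse
weather series to a fine recipe, where it reconstructs the underlying
continuous signal. Lighting commands are stored as volts on the 0–10 V dimming
line (a `light_pct` column is accepted and divided by 10).

The synthetic weather generator emulates a half-hourly coastal-temperate
diurnal record: a 24-h sinusoid whose extremes equal the requested bounds
(defaults 15.3–30.3 °C), minimum at 05:00 and maximum at 17:00, plus optional
seeded Gaussian noise clipped back into range. It reproduces the *range and
period* of a real record, not weather fronts, cloud events, or day-to-day
variation — so closed-loop results on it bound performance for smooth diurnal
recipes only, not for step-heavy or stochastic ones.

## Thermal plant

Temperature follows `dT/dt = k_mode (T_target − T) + k_leak (T_amb − T)`
(per-minute rates, explicit Euler at the caller's step; steps are a few tens
of seconds, far below the ~1/k stability limit). The drive targets are
interpreted as *supply-air* temperatures, not achievable cabinet states: the
cooling target is 0 °C with `k_cool = 0.009856 min⁻¹` and
`k_leak = 0.001 min⁻¹` toward a 25.4 °C ambient. Under these defaults the
instantaneous cooling rate at 25 °C is 0.246 °C·min⁻¹ and a one-hour pull-down
from 25.4 °C ends at 14.4 °C — both matching the reference bench, whose
observed 11.7 °C floor is the noise minimum around that steady state. A single
first-order pole with the floor itself as asymptote cannot satisfy both
measurements simultaneously, which is why the supply-air interpretation was
adopted. Heating uses `k_heat = 0.033907 min⁻¹` toward 38.6 °C (0.287 °C·min⁻¹
at 30 °C). Sensor noise defaults to 0.05 °C per step, i.i.d. Gaussian.

Humidity is a coarse first-order relaxation (0.05 min⁻¹ toward 60 % ambient,
4× faster under an active humidify/dry command) — enough to exercise the ±5 %
hysteresis controller, with no claim to psychrometric fidelity. DRY is
thermally identical to FAN but sinks RH toward 30 %.

## Actuator calibrations

* **Lighting:** PAR = 127.65·V + 12.15 µmol·m⁻²·s⁻¹ on [0.6, 9.7] V, zero
  below the 0.6 V activation threshold, clamped above 9.7 V saturation. The
  fitted line predicts 1250.4 at saturation where 1241 was measured; the
  module follows the fit and documents the ~0.8 % mismatch rather than mixing
  the two. The inverse maps sub-threshold targets to 0 V and rejects targets
  above saturation.
* **Irrigation:** fixed-rate pressure-compensated drippers at 1.24 L·h⁻¹
  (0.344 mL·s⁻¹); valve flow 0.34·u − 0.16 L·h⁻¹ for duty u ∈ [0, 1], clamped
  at zero — the negative intercept is treated as a regression dead-band.
* **Power:** a measured table — 68 W baseline; lighting 334 W at the 6.7 %
  activation threshold through 1936 W at 100 %, linearly interpolated between
  the printed levels and zero below threshold; climate modes 658/595/32 W
  (cool/heat/fan). The DRY draw was never characterised and defaults to the
  fan value (configurable). Night fan-only totals 100 W; full lighting with
  cooling totals 2594 W of actuators, 2662 W with baseline.

## Controller

Defaults: 10 s cycle, horizon clamped to [30, 90] s and chosen proportional to
error (|error| / max learned |rate| in minutes), w₁ = 1.0, w₂ = 0.1 with
ΔP = 1 for any mode change (the actuator set is discrete, so "change in
control action" is binary), 60 s minimum mode time, 120 s heat↔cool
stabilisation lockout, 0.3 °C early-termination band. The weights and the
horizon rule are design choices where only the ranges were externally fixed;
w₂ = 0.1 makes a mode switch cost as much as ~0.3 °C of sustained error over a
3-step horizon, enough to suppress chattering without delaying real
transitions. The rate table warm-starts at −0.246/+0.287 °C·min⁻¹ for
COOL/HEAT (the bench pull-down/heat-up rates) and 0 for passive modes; learned
rates are EMA-updated (α = 0.1) from the per-cycle first difference ΔT/Δt of
whichever mode was active, including cycles spanning recipe transitions. DRY
is never selected by the thermal cost — it belongs to humidity control — so
the cost stays a pure temperature objective. Ties break toward the
lowest-power mode (FAN > IDLE > DRY > HEAT/COOL).

Early termination (drop to FAN when |error| ≤ 0.3 °C while actively heating or
cooling) deliberately overrides both the cost minimisation and the minimum
on-time; it is the only permitted early mode exit.

## Heartbeats

Four cadences per cabinet on a simulated clock: 10 s sensor logging, 30 s
control, 60 s system, 3600 s imaging. The sensor logger is a separate cadence
from the control heartbeat — that is the only convention under which a 19-day
run yields both 164,160 readings (19·86400/10) and 456 images (19·24). Events
fire at t = k·interval for k ≥ 1, never at t = 0; coincident events execute
sensor → control → system → image. The scheduler jumps between events
(discrete-event, no fixed-step ticking), advancing the plant by the elapsed
interval, so a 19-day experiment completes in about five seconds. Fleet runs
share the event clock and derive per-cabinet RNG seeds from the master seed
via `numpy` seed sequences, so timestamps align across cabinets while noise
realisations differ.

## Phenotyping

`height_mm = maxRange × (1 − meanPixel/255)` over a plant mask; masks come
from a strict `pixel < threshold` rule (canopy is closer, hence darker, than
the background plane), with the mask argument exposed for manual regions.
Growth statistics are endpoint-based (total = last − first; rate = total /
week span), which makes them invariant to constant offsets applied to interior
points — deliberate, because transplanting and pot repositioning perturb
mid-series heights. The synthetic scene generator renders a rectangular canopy
at the 8-bit encoding of the requested height over a 255 background with
optional per-pixel noise; quantisation means arbitrary heights round to the
nearest 2000/255 ≈ 7.8 mm code, so exact round-trip holds only for
representable heights, and recovery from noisy scenes is accurate to well
under 1 % at 2-pixel noise over a 2400-pixel region.

## Metrics

Tracking error is temperature minus the recipe's active setpoint per sample.
The report carries MAE, extreme deviations, the percentage of samples inside
±0.5/1.0/1.5/2.0 °C, mean settle time (first entry into ±0.5 °C after each
setpoint change; never-settling steps are excluded), the error SD over stable
periods (samples ≥ 5 min after the latest change — the exclusion window is a
design choice, since "setpoint constant" alone was underspecified), per-mode
duty fractions (over decision counts, equivalent to wall time at a fixed
cycle), and transition counts. Thermal efficiency is rate / kW / m³ with the
11.17 m³ reference volume; reports print it to two significant figures and
keep the raw value. Reports serialise to schema-versioned, key-sorted JSON so
re-export is byte-identical.

## Problem sizes and determinism

The test suite and acceptance script use the study-scale runs directly — a
19-day heartbeat experiment and a 48-h diurnal closed loop — since the
discrete-event clock makes both cheap (seconds). All stochastic paths take
explicit integer seeds through `numpy.random.default_rng`; identical seeds
give bitwise-identical weather series, plant trajectories, and traces.

## Known limitations

* The plant is linear and first-order: no compressor start-up transients,
  no load from lamps or transpiration, no spatial gradients, no door events.
  Closed-loop MAE against it (~0.16 °C over 48 h) is therefore better than a
  physical cabinet would achieve (~0.76 °C on the reference bench); the
  simulation validates the *control logic*, not hardware precision.
* Humidity dynamics are schematic; only the hysteresis logic is meaningful.
* Phenotyping assumes a flat canopy and clean background; no RGB segmentation,
  leaf area, canopy volume, camera intrinsics, or point clouds.
* No network transport, database, or camera I/O; image heartbeats log
  manifest entries only.
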