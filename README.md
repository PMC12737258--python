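# growcab

A desk-scale toolkit for programmable plant-growth cabinets. It implements the
full software stack of a "smart" reach-in growth cabinet — climate-recipe
scheduling, an adaptive model-predictive temperature controller, heartbeat-driven
telemetry, actuator calibration models, and time-of-flight (ToF) plant-height
phenotyping — with the physical cabinet replaced by a simulated first-order
thermal plant, so every control and analysis component runs and is testable
end-to-end on a laptop, without instruments.

It is aimed at controlled-environment phenotyping groups who want to design,
stress-test, and analyse dynamic climate experiments (e.g. replaying a real
diurnal temperature record) before committing cabinet time, and at anyone
studying mode-switched HVAC control for growth chambers.

## The model and controller

**Plant.** Cabinet air temperature follows a two-term first-order model,
integrated with explicit Euler at the control step:

    dT/dt = k_mode (T_target,mode − T) + k_leak (T_amb − T)      [°C·min⁻¹]

COOL/HEAT apply their drive term; FAN/IDLE/DRY apply only the ambient leak.
Defaults are calibrated to a reference cabinet: cooling ≈ 0.246 °C·min⁻¹ near
25 °C, heating ≈ 0.287 °C·min⁻¹ near 30 °C, a one-hour pull-down from 25.4 °C
settling near 13.7 °C, and a heating ceiling near 38.6 °C.

**Controller.** Every 10 s cycle the controller learns each mode's thermal
response by exponential moving average and picks a mode by predictive cost:

    rate_new = (1 − α) rate_old + α rate_obs,         α = 0.1
    T(t+Δt)  = T(t) + rate_k Δt
    J        = Σᵢ w₁ (T(t+i) − T_sp)² + w₂ ΔP²

over an error-proportional horizon clamped to 30–90 s, subject to minimum
mode on-times, a heat↔cool stabilisation lockout, and early termination to
fan-only near the setpoint to prevent overshoot. Humidity uses ±5 % hysteresis.

**Phenotyping.** Height is recovered from 8-bit ToF amplitude PNGs (brighter =
farther, 255 = max range, 2000 mm default) over a thresholded plant region:

    height_mm = maxRange × (1 − pixelValue / 255)

Actuator calibrations: LED PAR = 127.65·V + 12.15 µmol·m⁻²·s⁻¹ on 0.6–9.7 V
(off below, saturated above); dripper flow 1.24 L·h⁻¹; valve flow
0.34·u − 0.16 L·h⁻¹ clamped at zero; a measured power table for
baseline/lighting/climate draws.

## Worked example

Generate a 48-h synthetic diurnal series (15.3–30.3 °C), convert it to a 30-s
recipe, and run the closed loop against the simulated cabinet:

```
$ growcab synth-weather --days 2 --tmin 15.3 --tmax 30.3 --seed 3 --out w.csv
wrote 96 samples to w.csv
$ growcab weather2recipe w.csv --spacing 30 --mode linear --out r.csv
wrote 5701 rows to r.csv
$ growcab simulate --recipe r.csv --duration-h 6 --seed 1 --out run1
MAE 0.192 °C over 2160 cycles; outputs in run1
```

The mean absolute error (MAE) is the average |temperature − setpoint| over all
2160 control cycles: the controller holds the moving diurnal setpoint to about
0.2 °C on average. `run1/trace.csv` holds the per-cycle temperature, setpoint,
mode and learned rates; `run1/report.json` the tracking report (deviation
bands, settle times, mode usage).

The same works in Python:

```python
from growcab import (PlantParams, generate_synthetic_weather,
                     weather_to_recipe, run_closed_loop, tracking_stats)

weather = generate_synthetic_weather(days=2, t_min=15.3, t_max=30.3, seed=3)
recipe = weather_to_recipe(weather, out_spacing_s=30, mode="linear")
trace = run_closed_loop(recipe, PlantParams(), duration_s=172_800, seed=1)
print(tracking_stats(trace, recipe).mae)   # ≈ 0.16 °C over 48 h
```

Other subcommands: `growcab validate-recipe`, `growcab run` (heartbeat-scheduled
multi-cabinet experiments with 10 s sensor logging, 30/60/3600 s control/system/
image heartbeats), `growcab phenotype` (heights from a directory of ToF PNGs),
`growcab report`.

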