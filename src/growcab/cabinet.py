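"""Simulated growth cabinet: thermal plant and calibrated actuator models.

The physical cabinet is a reach-in enclosure whose air temperature is
driven by a mode-switched split-system air conditioner (COOL / HEAT /
FAN / DRY / IDLE).  Here the enclosure is replaced by a two-term
first-order model integrated with explicit Euler:

    dT/dt = k_mode * (T_target_mode - T) + k_leak * (T_ambient - T)

(rates per minute).  FAN, IDLE and DRY apply only the ambient-leak term.
Default parameters are calibrated so the simulated plant reproduces the
bench-measured behaviour of the reference cabinet: a mean cooling rate of
about 0.246 °C·min⁻¹ near 25 °C, a mean heating rate of about
0.287 °C·min⁻¹ near 30 °C, a one-hour pull-down from 25.4 °C ambient
settling near 13.7 °C, and a heating ceiling near 38.6 °C.

Alongside the thermal plant sit pure actuator calibration curves:
LED PAR output versus dimming voltage, dripper irrigation volume, valve
duty-cycle flow, and a power-accounting table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import Enum

import numpy as np

__all__ = [
    "Mode",
    "ThermalState",
    "PlantParams",
    "PowerTable",
    "step_plant",
    "step_humidity",
    "lighting_par",
    "voltage_for_par",
    "irrigation_volume",
    "flow_from_signal",
    "power_draw",
    "PAR_SLOPE",
    "PAR_INTERCEPT",
    "PAR_ACTIVATION_V",
    "PAR_SATURATION_V",
    "DEFAULT_POWER_TABLE",
]


class Mode(str, Enum):
    """Air-conditioner operating mode; exactly one is active at a time."""

    COOL = "COOL"
    HEAT = "HEAT"
    FAN = "FAN"
    DRY = "DRY"
    IDLE = "IDLE"


@dataclass(frozen=True)
class ThermalState:
    """Cabinet air state at simulation time ``t`` (seconds)."""

    t: float
    temp: float
    rh: float = 60.0

    def __post_init__(self) -> None:
        if not math.isfinite(self.temp):
            raise ValueError("temperature must be finite")
        if not 0.0 <= self.rh <= 100.0:
            raise ValueError("relative humidity outside [0, 100]")


@dataclass(frozen=True)
class PlantParams:
    """First-order thermal plant parameters.

    ``k_cool``/``k_heat`` are per-minute gains toward the mode drive
    targets; ``k_leak`` couples the cabinet to ambient.  The drive
    targets are *supply-air* temperatures, well beyond the steady states
    the cabinet air actually reaches: with the defaults the effective
    cooling steady state sits near 13–14 °C (observed floor 11.7 °C with
    sensor noise) and the heating ceiling near 38 °C.
    """

    k_cool: float = 0.009856
    k_heat: float = 0.033907
    T_cool_target: float = 0.0
    T_heat_target: float = 38.6
    k_leak: float = 0.001
    T_ambient: float = 25.4
    noise_sd: float = 0.05
    seed: int = 0
    # Coarse humidity dynamics: relaxation per minute toward a target.
    k_rh: float = 0.05
    rh_ambient: float = 60.0
    rh_dry_target: float = 30.0

    def __post_init__(self) -> None:
        if self.k_cool < 0 or self.k_heat < 0 or self.k_leak < 0:
            raise ValueError("gains must be >= 0")
        if self.T_cool_target >= self.T_heat_target:
            raise ValueError("T_cool_target must be below T_heat_target")


def step_plant(
    state: ThermalState,
    mode: Mode,
    dt: float,
    params: PlantParams,
    rng: np.random.Generator | None = None,
) -> ThermalState:
    """Advance the thermal plant by ``dt`` seconds under ``mode``.

    Explicit Euler on the two-term first-order model; COOL/HEAT apply
    their drive term plus the ambient leak, FAN/IDLE/DRY the leak only.
    Gaussian noise of ``params.noise_sd`` °C is added per step when an
    ``rng`` is supplied.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    temp = state.temp
    drive = 0.0
    if mode == Mode.COOL:
        drive = params.k_cool * (params.T_cool_target - temp)
    elif mode == Mode.HEAT:
        drive = params.k_heat * (params.T_heat_target - temp)
    leak = params.k_leak * (params.T_ambient - temp)
    temp = temp + dt * (drive + leak) / 60.0
    if rng is not None and params.noise_sd > 0:
        temp += rng.normal(0.0, params.noise_sd)
    rh = step_humidity(state.rh, mode, None, dt, params)
    return ThermalState(t=state.t + dt, temp=temp, rh=rh)


def step_humidity(
    rh: float,
    mode: Mode,
    command: str | None,
    dt: float,
    params: PlantParams,
) -> float:
    """Coarse first-order humidity update.

    DRY mode (or an explicit ``"dry"`` command) relaxes RH toward the
    dehumidified target; a ``"humidify"`` command relaxes toward
    saturation; otherwise RH drifts toward ambient.  Fidelity beyond a
    ±5 % control band is out of scope.
    """
    if command == "humidify":
        target = 95.0
        k = params.k_rh * 4
    elif command == "dry" or mode == Mode.DRY:
        target = params.rh_dry_target
        k = params.k_rh * 4
    else:
        target = params.rh_ambient
        k = params.k_rh
    rh = rh + dt * k * (target - rh) / 60.0
    return min(100.0, max(0.0, rh))


# --- LED lighting calibration (PAR vs 0-10 V dimming command) ---------------

PAR_SLOPE = 127.65  # µmol·m⁻²·s⁻¹ per volt in the linear band
PAR_INTERCEPT = 12.15
PAR_ACTIVATION_V = 0.6  # LED array off below this command
PAR_SATURATION_V = 9.7  # output saturates above this command


def lighting_par(voltage: float) -> float:
    """PAR output (µmol·m⁻²·s⁻¹) for a 0–10 V dimming command.

    Zero below the 0.6 V activation threshold; linear
    ``127.65·V + 12.15`` on [0.6, 9.7] V; clamped to the 9.7 V value
    above saturation.  The regression predicts 1250.4 µmol·m⁻²·s⁻¹ at
    saturation versus a measured maximum of 1241; this module follows the
    fitted line.
    """
    if not 0.0 <= voltage <= 10.0:
        raise ValueError(f"voltage {voltage} outside [0, 10] V")
    if voltage < PAR_ACTIVATION_V:
        return 0.0
    v = min(voltage, PAR_SATURATION_V)
    return PAR_SLOPE * v + PAR_INTERCEPT


#: Maximum achievable PAR (linear model at the 9.7 V saturation point).
PAR_MAX = PAR_SLOPE * PAR_SATURATION_V + PAR_INTERCEPT


def voltage_for_par(target: float) -> float:
    """Invert the PAR calibration: dimming voltage for a PAR target.

    Targets below the activation-threshold output map to 0 V (lights
    off); targets above the saturation output are an error.
    """
    if target < 0:
        raise ValueError("PAR target must be >= 0")
    if target > PAR_MAX + 1e-9:
        raise ValueError(
            f"PAR target {target} above saturation output {PAR_MAX:.1f}"
        )
    threshold_par = PAR_SLOPE * PAR_ACTIVATION_V + PAR_INTERCEPT
    if target < threshold_par:
        return 0.0
    return (target - PAR_INTERCEPT) / PAR_SLOPE


# --- Irrigation -------------------------------------------------------------


def irrigation_volume(duration_s: float, flow_lph: float = 1.24) -> float:
    """Millilitres delivered by a dripper running ``duration_s`` seconds.

    The pressure-compensated drippers deliver a fixed 1.24 L·h⁻¹
    (±0.09) by default.
    """
    if duration_s < 0:
        raise ValueError("duration_s must be >= 0")
    if flow_lph < 0:
        raise ValueError("flow_lph must be >= 0")
    return flow_lph * 1000.0 * duration_s / 3600.0


def flow_from_signal(u: float) -> float:
    """Valve flow (L·h⁻¹) from a 0–1 PWM duty-cycle signal.

    Fitted line ``0.34·u − 0.16`` clamped at zero: the negative
    intercept is a dead-band artifact of the regression, not reverse
    flow.
    """
    if not 0.0 <= u <= 1.0:
        raise ValueError(f"duty cycle {u} outside calibrated range [0, 1]")
    return max(0.0, 0.34 * u - 0.16)


# --- Power accounting -------------------------------------------------------

#: Lighting intensity (% of full scale) at the LED activation threshold,
#: i.e. 83 of 1241 µmol·m⁻²·s⁻¹.
LIGHTING_THRESHOLD_PCT = 100.0 * 83.0 / 1241.0


@dataclass(frozen=True)
class PowerTable:
    """Measured subsystem power draws (watts).

    ``lighting_points`` are (intensity %, watts) pairs from the LED
    activation threshold up to 100 %; draws between points are linearly
    interpolated and the array consumes nothing below threshold.
    """

    baseline_w: float = 68.0
    lighting_points: tuple[tuple[float, float], ...] = (
        (LIGHTING_THRESHOLD_PCT, 334.0),
        (25.0, 1003.0),
        (50.0, 1253.0),
        (75.0, 1543.0),
        (100.0, 1936.0),
    )
    mode_w: dict[Mode, float] = field(
        default_factory=lambda: {
            Mode.COOL: 658.0,
            Mode.HEAT: 595.0,
            Mode.FAN: 32.0,
            Mode.DRY: 32.0,  # dehumidify draw was not characterised; fan-level
            Mode.IDLE: 0.0,
        }
    )

    def __post_init__(self) -> None:
        if self.baseline_w < 0 or any(w < 0 for _, w in self.lighting_points):
            raise ValueError("watts must be >= 0")
        watts = [w for _, w in self.lighting_points]
        if any(b < a for a, b in zip(watts, watts[1:])):
            raise ValueError("lighting watts must be non-decreasing")


DEFAULT_POWER_TABLE = PowerTable()


def power_draw(
    lighting_pct: float,
    mode: Mode,
    include_baseline: bool = True,
    table: PowerTable = DEFAULT_POWER_TABLE,
) -> float:
    """Total system draw (W) at a lighting intensity and climate mode."""
    if not 0.0 <= lighting_pct <= 100.0:
        raise ValueError(f"lighting_pct {lighting_pct} outside [0, 100]")
    pts = table.lighting_points
    if lighting_pct < pts[0][0]:
        lighting_w = 0.0
    else:
        xs = [p for p, _ in pts]
        ys = [w for _, w in pts]
        lighting_w = float(np.interp(lighting_pct, xs, ys))
    total = lighting_w + table.mode_w[mode]
    if include_baseline:
        total += table.baseline_w
    return total
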