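"""Adaptive model-predictive temperature control.

Every control cycle (10 s by default) the controller

1. measures cabinet temperature and humidity,
2. updates its learned per-mode thermal response rate with an
   exponential moving average,
       rate_new = (1 - α) · rate_old + α · observed_rate,      α = 0.1
3. predicts the temperature trajectory under each candidate mode,
       T(t + Δt) = T(t) + rate_k · Δt,
4. picks the mode minimising the quadratic tracking cost
       J = Σ_i [ w1 · (T(t+i) - T_sp)² ] + w2 · ΔP²,
   subject to minimum on-times and a stabilisation lockout between
   heating and cooling, and
5. drops back to fan-only as soon as the temperature enters a small band
   around the setpoint while actively heating or cooling ("early
   termination", preventing overshoot).

ΔP is 1 for any mode change and 0 otherwise — the appliance is
mode-switched, so the "change in control action" is binary.  Humidity is
handled by simple hysteresis, not by the predictive cost.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import Enum

import numpy as np
import pandas as pd

from .cabinet import Mode, PlantParams, ThermalState, step_humidity, step_plant
from .recipes import Recipe, active_setpoint

__all__ = [
    "RateTable",
    "ControllerConfig",
    "ControlDecision",
    "ModeHistory",
    "HumidityCommand",
    "update_rate",
    "predict_temperature",
    "action_cost",
    "select_action",
    "control_humidity",
    "run_closed_loop",
    "ClosedLoopTrace",
    "THERMAL_CANDIDATES",
    "MODE_PRIORITY",
]

#: Modes the thermal cost may choose between.  DRY participates in
#: humidity control only; keeping it out keeps the cost a pure
#: temperature objective.
THERMAL_CANDIDATES = (Mode.FAN, Mode.IDLE, Mode.HEAT, Mode.COOL)

#: Tie-break order (prefer lowest power): FAN > IDLE > DRY > HEAT/COOL.
MODE_PRIORITY = {
    Mode.FAN: 0,
    Mode.IDLE: 1,
    Mode.DRY: 2,
    Mode.HEAT: 3,
    Mode.COOL: 4,
}


def update_rate(rate_old: float, observed_rate: float, alpha: float = 0.1) -> float:
    """Exponential-moving-average update of a learned thermal rate."""
    if not 0.0 < alpha <= 1.0:
        raise ValueError("alpha must be in (0, 1]")
    if not (math.isfinite(rate_old) and math.isfinite(observed_rate)):
        raise ValueError("rates must be finite")
    return (1.0 - alpha) * rate_old + alpha * observed_rate


def predict_temperature(temp: float, rate_k: float, dt: float) -> float:
    """Linear temperature forecast: ``temp + rate_k · dt`` (rate per minute)."""
    if dt < 0:
        raise ValueError("dt must be >= 0")
    return temp + rate_k * (dt / 60.0)


def action_cost(
    predicted_temps: list[float] | tuple[float, ...],
    t_sp: float,
    delta_p: float,
    w1: float = 1.0,
    w2: float = 0.1,
) -> float:
    """Quadratic tracking cost over a prediction horizon.

    ``Σ w1·(T - T_sp)² + w2·ΔP²``; the control-change penalty is added
    once per evaluated action.
    """
    if len(predicted_temps) == 0:
        raise ValueError("prediction list must be non-empty")
    j = sum(w1 * (t - t_sp) ** 2 for t in predicted_temps)
    return j + w2 * delta_p**2


@dataclass
class RateTable:
    """Learned per-mode thermal response rates (°C·min⁻¹).

    Warm-started from the bench-measured cooling/heating rates
    (−0.246 / +0.287 °C·min⁻¹) so the controller is sane before it has
    learned anything.
    """

    rates: dict[Mode, float] = field(
        default_factory=lambda: {
            Mode.COOL: -0.246,
            Mode.HEAT: 0.287,
            Mode.FAN: 0.0,
            Mode.IDLE: 0.0,
            Mode.DRY: 0.0,
        }
    )
    alpha: float = 0.1

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha <= 1.0:
            raise ValueError("alpha must be in (0, 1]")

    def update(self, mode: Mode, observed_rate: float) -> None:
        self.rates[mode] = update_rate(self.rates[mode], observed_rate, self.alpha)

    def copy(self) -> "RateTable":
        return RateTable(rates=dict(self.rates), alpha=self.alpha)


@dataclass(frozen=True)
class ControllerConfig:
    """Tunable control parameters.

    The prediction horizon is picked per cycle, proportional to the
    tracking error but clamped to [horizon_min_s, horizon_max_s];
    ``min_mode_s`` and ``stabilize_s`` protect the compressor from short
    cycling and from direct heat/cool reversals.
    """

    cycle_s: float = 10.0
    horizon_min_s: float = 30.0
    horizon_max_s: float = 90.0
    w1: float = 1.0
    w2: float = 0.1
    min_mode_s: float = 60.0
    stabilize_s: float = 120.0
    early_stop_band: float = 0.3

    def __post_init__(self) -> None:
        if not 0 < self.horizon_min_s <= self.horizon_max_s:
            raise ValueError("need 0 < horizon_min_s <= horizon_max_s")
        if self.w1 <= 0 or self.w2 < 0:
            raise ValueError("need w1 > 0 and w2 >= 0")
        if self.cycle_s <= 0:
            raise ValueError("cycle_s must be positive")


@dataclass
class ModeHistory:
    """What the controller needs to remember about recent actuation."""

    mode: Mode = Mode.FAN
    since_s: float = 0.0  # time the current mode was entered
    last_heat_s: float = -math.inf  # last instant HEAT was active
    last_cool_s: float = -math.inf

    def advance(self, mode: Mode, t: float, dt: float) -> None:
        """Record that ``mode`` ran over [t, t + dt)."""
        if mode != self.mode:
            self.mode = mode
            self.since_s = t
        if mode == Mode.HEAT:
            self.last_heat_s = t + dt
        elif mode == Mode.COOL:
            self.last_cool_s = t + dt


@dataclass(frozen=True)
class ControlDecision:
    mode: Mode
    horizon_s: float
    predicted_temp: float
    costs: dict[Mode, float]
    early_termination: bool = False


def _pick_horizon(error: float, rates: RateTable, config: ControllerConfig) -> float:
    """Error-proportional horizon, clamped to the configured band."""
    fastest = max(abs(rates.rates[Mode.COOL]), abs(rates.rates[Mode.HEAT]), 1e-6)
    h = abs(error) / fastest * 60.0
    return min(max(h, config.horizon_min_s), config.horizon_max_s)


def select_action(
    state: ThermalState,
    setpoint: float,
    rates: RateTable,
    config: ControllerConfig,
    history: ModeHistory,
) -> ControlDecision:
    """Choose the next operating mode for one control cycle.

    Candidates are restricted by the minimum on-time (the current mode
    must be kept until ``min_mode_s`` elapses, except for early
    termination) and by the heat/cool stabilisation lockout (no entering
    COOL within ``stabilize_s`` of HEAT being active, and vice versa).
    Among admissible modes the minimal-J one wins; exact ties go to the
    lower-power mode.
    """
    t = state.t
    error = state.temp - setpoint
    horizon = _pick_horizon(error, rates, config)
    n_steps = max(1, int(horizon // config.cycle_s))

    # Early termination: approaching target while actively driving.
    if history.mode in (Mode.HEAT, Mode.COOL) and abs(error) <= config.early_stop_band:
        pred = predict_temperature(state.temp, rates.rates[Mode.FAN], horizon)
        return ControlDecision(
            mode=Mode.FAN,
            horizon_s=horizon,
            predicted_temp=pred,
            costs={},
            early_termination=True,
        )

    if t - history.since_s < config.min_mode_s:
        candidates = [history.mode]
    else:
        candidates = []
        for m in THERMAL_CANDIDATES:
            if m == Mode.COOL and t - history.last_heat_s < config.stabilize_s:
                continue
            if m == Mode.HEAT and t - history.last_cool_s < config.stabilize_s:
                continue
            candidates.append(m)

    costs: dict[Mode, float] = {}
    for m in candidates:
        preds = [
            predict_temperature(state.temp, rates.rates[m], (i + 1) * config.cycle_s)
            for i in range(n_steps)
        ]
        delta_p = 0.0 if m == history.mode else 1.0
        costs[m] = action_cost(preds, setpoint, delta_p, config.w1, config.w2)

    best = min(candidates, key=lambda m: (costs[m], MODE_PRIORITY[m]))
    pred = predict_temperature(state.temp, rates.rates[best], horizon)
    return ControlDecision(mode=best, horizon_s=horizon, predicted_temp=pred, costs=costs)


class HumidityCommand(str, Enum):
    HUMIDIFY = "humidify"
    DRY = "dry"
    HOLD = "hold"


def control_humidity(rh: float, rh_sp: float, band: float = 5.0) -> HumidityCommand:
    """Hysteresis humidity control with a ±``band`` % tolerance."""
    if band <= 0:
        raise ValueError("band must be positive")
    if not 0.0 <= rh <= 100.0:
        raise ValueError("rh outside [0, 100]")
    if rh < rh_sp - band:
        return HumidityCommand.HUMIDIFY
    if rh > rh_sp + band:
        return HumidityCommand.DRY
    return HumidityCommand.HOLD


@dataclass
class ClosedLoopTrace:
    """Per-cycle record of a closed-loop run."""

    t_s: list[float] = field(default_factory=list)
    temp_c: list[float] = field(default_factory=list)
    rh_pct: list[float] = field(default_factory=list)
    setpoint_c: list[float] = field(default_factory=list)
    mode: list[Mode] = field(default_factory=list)
    cost_j: list[float] = field(default_factory=list)
    rate_cool: list[float] = field(default_factory=list)
    rate_heat: list[float] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.t_s)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "t_s": self.t_s,
                "temp_c": self.temp_c,
                "setpoint_c": self.setpoint_c,
                "mode": [m.value for m in self.mode],
                "J": self.cost_j,
                "learned_rate_cool": self.rate_cool,
                "learned_rate_heat": self.rate_heat,
            }
        )

    def to_csv(self) -> str:
        return self.to_frame().to_csv(index=False)


def run_closed_loop(
    recipe: Recipe,
    plant: PlantParams,
    config: ControllerConfig | None = None,
    duration_s: float = 3600.0,
    seed: int = 0,
    rates: RateTable | None = None,
    initial_temp: float | None = None,
) -> ClosedLoopTrace:
    """Run the controller against the simulated plant.

    One decision per control cycle; the observed rate over each cycle
    (first difference ΔT/Δt, °C·min⁻¹) feeds the EMA for whichever mode
    was active.  Identical seeds and configs give identical traces.
    """
    config = config or ControllerConfig()
    if duration_s < config.cycle_s:
        raise ValueError("duration_s must cover at least one control cycle")
    rng = np.random.default_rng(seed)
    rates = rates.copy() if rates is not None else RateTable()
    first = recipe.rows[0]
    state = ThermalState(
        t=0.0,
        temp=first.temp_sp if initial_temp is None else initial_temp,
        rh=first.rh_sp,
    )
    history = ModeHistory(mode=Mode.FAN, since_s=0.0)
    trace = ClosedLoopTrace()
    n_cycles = int(duration_s // config.cycle_s)
    for i in range(n_cycles):
        t = i * config.cycle_s
        sp = active_setpoint(recipe, t)
        decision = select_action(state, sp.temp_sp, rates, config, history)
        hum_cmd = control_humidity(state.rh, sp.rh_sp)
        trace.t_s.append(t)
        trace.temp_c.append(state.temp)
        trace.rh_pct.append(state.rh)
        trace.setpoint_c.append(sp.temp_sp)
        trace.mode.append(decision.mode)
        trace.cost_j.append(decision.costs.get(decision.mode, 0.0))
        trace.rate_cool.append(rates.rates[Mode.COOL])
        trace.rate_heat.append(rates.rates[Mode.HEAT])
        new_state = step_plant(state, decision.mode, config.cycle_s, plant, rng)
        rh = step_humidity(state.rh, decision.mode, hum_cmd.value, config.cycle_s, plant)
        new_state = ThermalState(t=new_state.t, temp=new_state.temp, rh=rh)
        observed = (new_state.temp - state.temp) / (config.cycle_s / 60.0)
        rates.update(decision.mode, observed)
        history.advance(decision.mode, t, config.cycle_s)
        state = new_state
    return trace
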