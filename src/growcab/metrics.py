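"""Closed-loop tracking statistics, thermal efficiency, and reports.

Summarises controller traces the way climate-control benches are
reported: mean absolute tracking error, worst-case deviations, the
fraction of samples inside ±0.5/±1.0/±1.5/±2.0 °C bands, settle times
after setpoint steps, per-mode duty fractions, and a volume-normalised
thermal-efficiency figure (°C·min⁻¹ per kW per m³).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

from .cabinet import Mode
from .mpc import ClosedLoopTrace
from .recipes import Recipe, active_setpoint

__all__ = [
    "TrackingReport",
    "EfficiencyFigure",
    "tracking_stats",
    "traverse_time",
    "thermal_efficiency",
    "export_report",
    "SETTLE_BAND_C",
    "STABLE_EXCLUSION_S",
    "CABINET_VOLUME_M3",
]

#: Band used for settle-time measurement after a setpoint change.
SETTLE_BAND_C = 0.5
#: Samples within this window after a setpoint change are excluded from
#: the "stable period" error SD.
STABLE_EXCLUSION_S = 300.0
#: Interior volume of the reference cabinet.
CABINET_VOLUME_M3 = 11.17

BAND_WIDTHS_C = (0.5, 1.0, 1.5, 2.0)


@dataclass(frozen=True)
class TrackingReport:
    """Closed-loop temperature tracking summary."""

    mae: float
    max_pos_dev: float
    max_neg_dev: float
    stable_sd: float
    band_fractions: dict[float, float]  # band width °C -> % of samples inside
    mean_settle_min: float
    mode_usage: dict[Mode, float]
    transitions: int

    def to_dict(self) -> dict:
        return {
            "mae_c": self.mae,
            "max_pos_dev_c": self.max_pos_dev,
            "max_neg_dev_c": self.max_neg_dev,
            "stable_sd_c": self.stable_sd,
            "band_fractions_pct": {str(k): v for k, v in self.band_fractions.items()},
            "mean_settle_min": self.mean_settle_min,
            "mode_usage": {m.value: v for m, v in self.mode_usage.items()},
            "transitions": self.transitions,
        }


@dataclass(frozen=True)
class EfficiencyFigure:
    """Thermal rate per unit electrical power, volume-normalised."""

    rate: float  # °C·min⁻¹
    power_kw: float
    volume_m3: float
    efficiency: float  # °C·min⁻¹·kW⁻¹·m⁻³

    @property
    def efficiency_2sf(self) -> float:
        """Efficiency rounded to two significant figures for display."""
        if self.efficiency == 0:
            return 0.0
        exp = math.floor(math.log10(abs(self.efficiency)))
        return round(self.efficiency, 1 - exp)

    def to_dict(self) -> dict:
        return {
            "rate_c_per_min": self.rate,
            "power_kw": self.power_kw,
            "volume_m3": self.volume_m3,
            "efficiency": self.efficiency,
            "efficiency_2sf": self.efficiency_2sf,
        }


def tracking_stats(trace: ClosedLoopTrace, recipe: Recipe) -> TrackingReport:
    """Compute tracking statistics for a closed-loop trace.

    Error is measured against the recipe's active setpoint at each
    sample.  Settle time is measured from each setpoint change to the
    first sample within ±0.5 °C of the new target; steps that never
    settle within the trace are excluded from the mean.
    """
    if len(trace) == 0:
        raise ValueError("trace is empty")
    t = np.asarray(trace.t_s)
    temp = np.asarray(trace.temp_c)
    sp = np.array([active_setpoint(recipe, float(ti)).temp_sp for ti in t])
    err = temp - sp

    mae = float(np.mean(np.abs(err)))
    max_pos = float(err.max())
    max_neg = float(err.min())
    bands = {
        w: float(np.mean(np.abs(err) <= w) * 100.0) for w in BAND_WIDTHS_C
    }

    # Setpoint-change indices and per-sample time since last change.
    change_idx = np.flatnonzero(np.diff(sp) != 0) + 1
    last_change_t = np.zeros_like(t)
    prev = t[0]
    ci = 0
    for i in range(len(t)):
        if ci < len(change_idx) and i == change_idx[ci]:
            prev = t[i]
            ci += 1
        last_change_t[i] = prev
    stable = (t - last_change_t) >= STABLE_EXCLUSION_S
    # With no change in the first window, measure stability from t >= window.
    stable |= (len(change_idx) == 0) & (t >= STABLE_EXCLUSION_S)
    stable_sd = float(np.std(err[stable])) if stable.any() else float("nan")

    settles = []
    for i in change_idx:
        inside = np.flatnonzero(np.abs(err[i:]) <= SETTLE_BAND_C)
        if inside.size:
            settles.append((t[i + inside[0]] - t[i]) / 60.0)
    mean_settle = float(np.mean(settles)) if settles else 0.0

    n = len(trace.mode)
    usage = {m: trace.mode.count(m) / n for m in Mode}
    transitions = sum(
        1 for a, b in zip(trace.mode, trace.mode[1:]) if a != b
    )
    return TrackingReport(
        mae=mae,
        max_pos_dev=max_pos,
        max_neg_dev=max_neg,
        stable_sd=stable_sd,
        band_fractions=bands,
        mean_settle_min=mean_settle,
        mode_usage=usage,
        transitions=transitions,
    )


def traverse_time(delta_t: float, rate: float) -> float:
    """Minutes to traverse ``delta_t`` °C at ``rate`` °C·min⁻¹."""
    if rate <= 0:
        raise ValueError("rate magnitude must be positive")
    if delta_t < 0:
        raise ValueError("delta_t must be >= 0")
    return delta_t / rate


def thermal_efficiency(
    rate: float, power_w: float, volume_m3: float = CABINET_VOLUME_M3
) -> EfficiencyFigure:
    """Temperature-change rate per kW of draw, normalised to cabinet volume."""
    if rate <= 0 or power_w <= 0 or volume_m3 <= 0:
        raise ValueError("rate, power and volume must be positive")
    power_kw = power_w / 1000.0
    return EfficiencyFigure(
        rate=rate,
        power_kw=power_kw,
        volume_m3=volume_m3,
        efficiency=rate / power_kw / volume_m3,
    )


REPORT_SCHEMA_VERSION = "1"


def export_report(
    tracking: TrackingReport | None = None,
    efficiency: EfficiencyFigure | None = None,
    run_summary: dict | None = None,
    path: str | None = None,
) -> str:
    """Serialise a report to schema-stable JSON (idempotent re-export)."""
    if tracking is None and efficiency is None and run_summary is None:
        raise ValueError("report has no content")
    doc: dict = {"schema_version": REPORT_SCHEMA_VERSION}
    if tracking is not None:
        doc["tracking"] = tracking.to_dict()
    if efficiency is not None:
        doc["efficiency"] = efficiency.to_dict()
    if run_summary is not None:
        doc["run"] = run_summary
    text = json.dumps(doc, indent=2, sort_keys=True)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text
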