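"""Plain-text ``key = value`` configuration files.

Schema (all keys optional; unknown keys rejected):

Plant file — fields of :class:`growcab.cabinet.PlantParams`, e.g.::

    k_cool = 0.009856
    T_ambient = 25.4
    noise_sd = 0.05

Controller file — fields of :class:`growcab.mpc.ControllerConfig`.

Power file — ``baseline_w``, per-mode ``cool_w``/``heat_w``/``fan_w``/
``dry_w``/``idle_w``, and ``lighting_points`` as comma-separated
``pct:watts`` pairs, e.g. ``lighting_points = 6.69:334, 25:1003, 100:1936``.

Lines starting with ``#`` are comments.
"""

from __future__ import annotations

from dataclasses import fields

from .cabinet import Mode, PlantParams, PowerTable
from .mpc import ControllerConfig

__all__ = [
    "parse_kv",
    "load_plant_params",
    "load_controller_config",
    "load_power_table",
]


def parse_kv(text: str) -> dict[str, str]:
    """Parse ``key = value`` lines, ignoring blanks and ``#`` comments."""
    out: dict[str, str] = {}
    for lineno, raw in enumerate(text.splitlines(), 1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise ValueError(f"line {lineno}: expected 'key = value', got {raw!r}")
        key, _, value = line.partition("=")
        out[key.strip()] = value.strip()
    return out


def _load_dataclass(cls, text: str):
    kv = parse_kv(text)
    valid = {f.name: f.type for f in fields(cls)}
    kwargs = {}
    for key, value in kv.items():
        if key not in valid:
            raise ValueError(f"unknown {cls.__name__} key {key!r}")
        kwargs[key] = int(value) if key == "seed" else float(value)
    return cls(**kwargs)


def load_plant_params(text: str) -> PlantParams:
    return _load_dataclass(PlantParams, text)


def load_controller_config(text: str) -> ControllerConfig:
    return _load_dataclass(ControllerConfig, text)


_MODE_KEYS = {
    "cool_w": Mode.COOL,
    "heat_w": Mode.HEAT,
    "fan_w": Mode.FAN,
    "dry_w": Mode.DRY,
    "idle_w": Mode.IDLE,
}


def load_power_table(text: str) -> PowerTable:
    kv = parse_kv(text)
    defaults = PowerTable()
    baseline = defaults.baseline_w
    points = defaults.lighting_points
    mode_w = dict(defaults.mode_w)
    for key, value in kv.items():
        if key == "baseline_w":
            baseline = float(value)
        elif key == "lighting_points":
            pairs = []
            for chunk in value.split(","):
                pct, _, watts = chunk.partition(":")
                pairs.append((float(pct), float(watts)))
            points = tuple(pairs)
        elif key in _MODE_KEYS:
            mode_w[_MODE_KEYS[key]] = float(value)
        else:
            raise ValueError(f"unknown PowerTable key {key!r}")
    return PowerTable(baseline_w=baseline, lighting_points=points, mode_w=mode_w)
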