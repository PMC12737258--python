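"""Climate recipes: validated schedules of environmental setpoints.

A *recipe* is a time-ordered table of setpoints a growth cabinet executes:
target air temperature (°C), relative humidity (%), a 0–10 V lighting
dimming command, and irrigation pulses (seconds of watering).  Rows are
offsets from experiment start and may be spaced no finer than 30 s.
Between rows the setpoint is held constant (zero-order hold, left-closed
intervals) and the last row holds forever.

The module also converts half-hourly outdoor temperature series into
fine-grained recipes for weather-replay experiments, and generates
synthetic diurnal series standing in for downloaded station data.
"""

from __future__ import annotations

import io
import math
from bisect import bisect_right
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "SetpointRow",
    "Recipe",
    "WeatherSeries",
    "RecipeError",
    "RecipeColumnError",
    "RecipeOrderError",
    "RecipeSpacingError",
    "RecipeRangeError",
    "MIN_ROW_SPACING_S",
    "parse_recipe",
    "write_recipe",
    "active_setpoint",
    "weather_to_recipe",
    "generate_synthetic_weather",
    "parse_weather",
    "write_weather",
]

#: Finest allowed spacing between consecutive recipe rows, in seconds.
MIN_ROW_SPACING_S = 30.0

RECIPE_COLUMNS = ("offset_s", "temp_c", "rh_pct", "light_v", "irrigation_s")


class RecipeError(ValueError):
    """Base class for recipe validation failures."""


class RecipeColumnError(RecipeError):
    """A required column is missing from the CSV header."""


class RecipeOrderError(RecipeError):
    """Row offsets are not strictly increasing (or first row not at 0)."""


class RecipeSpacingError(RecipeError):
    """Consecutive rows are closer than the 30 s minimum."""


class RecipeRangeError(RecipeError):
    """A setpoint value is outside its physical range."""


@dataclass(frozen=True)
class SetpointRow:
    """One scheduled setpoint.

    Parameters
    ----------
    offset_s : float
        Seconds from experiment start (>= 0).
    temp_sp : float
        Target air temperature, °C.
    rh_sp : float
        Target relative humidity, % (0–100).
    light_cmd : float
        Lighting dimming command, volts on the 0–10 V control line.
    irrigation_s : float
        Seconds of watering triggered at this offset (0 = none).
    """

    offset_s: float
    temp_sp: float
    rh_sp: float
    light_cmd: float
    irrigation_s: float = 0.0

    def validate(self, row_index: int) -> None:
        if self.offset_s < 0:
            raise RecipeRangeError(f"row {row_index}: offset_s must be >= 0")
        if not math.isfinite(self.temp_sp):
            raise RecipeRangeError(f"row {row_index}: temp_c must be finite")
        if not 0.0 <= self.rh_sp <= 100.0:
            raise RecipeRangeError(
                f"row {row_index}: rh_pct {self.rh_sp} outside [0, 100]"
            )
        if not 0.0 <= self.light_cmd <= 10.0:
            raise RecipeRangeError(
                f"row {row_index}: light_v {self.light_cmd} outside [0, 10]"
            )
        if self.irrigation_s < 0:
            raise RecipeRangeError(f"row {row_index}: irrigation_s must be >= 0")


@dataclass(frozen=True)
class Recipe:
    """A validated, time-ordered setpoint schedule."""

    rows: tuple[SetpointRow, ...]
    recipe_id: str = "recipe"
    version: str = "1"

    def __post_init__(self) -> None:
        if not self.rows:
            raise RecipeError("recipe has no rows")
        for i, row in enumerate(self.rows):
            row.validate(i)
        if self.rows[0].offset_s != 0:
            raise RecipeOrderError("row 0: first row must be at offset 0")
        for i in range(1, len(self.rows)):
            gap = self.rows[i].offset_s - self.rows[i - 1].offset_s
            if gap <= 0:
                raise RecipeOrderError(
                    f"row {i}: offsets not strictly increasing "
                    f"({self.rows[i].offset_s} after {self.rows[i - 1].offset_s})"
                )
            if gap < MIN_ROW_SPACING_S:
                raise RecipeSpacingError(
                    f"row {i}: spacing {gap:g} s below minimum "
                    f"{MIN_ROW_SPACING_S:g} s"
                )
        # Offsets cache for O(log n) setpoint lookup.
        object.__setattr__(self, "_offsets", [r.offset_s for r in self.rows])

    def __len__(self) -> int:
        return len(self.rows)

    @property
    def duration_s(self) -> float:
        return self.rows[-1].offset_s


@dataclass(frozen=True)
class WeatherSeries:
    """Uniformly spaced outdoor temperature samples."""

    offsets_s: tuple[float, ...]
    temps_c: tuple[float, ...]
    spacing_s: float

    def __post_init__(self) -> None:
        if self.spacing_s <= 0:
            raise ValueError("spacing_s must be positive")
        if len(self.offsets_s) != len(self.temps_c):
            raise ValueError("offsets and temperatures differ in length")
        if not self.offsets_s:
            raise ValueError("weather series is empty")
        for i in range(1, len(self.offsets_s)):
            if not math.isclose(
                self.offsets_s[i] - self.offsets_s[i - 1], self.spacing_s
            ):
                raise ValueError(f"non-uniform spacing at sample {i}")
        if not all(math.isfinite(t) for t in self.temps_c):
            raise ValueError("non-finite temperature in weather series")

    def __len__(self) -> int:
        return len(self.offsets_s)


def parse_recipe(csv_text: str, recipe_id: str = "recipe", version: str = "1") -> Recipe:
    """Parse a recipe CSV into a validated :class:`Recipe`.

    The dialect is comma-separated UTF-8 with header
    ``offset_s,temp_c,rh_pct,light_v,irrigation_s`` and '.' decimals.
    A ``light_pct`` column (0–100 %) is accepted in place of ``light_v``
    and converted to volts (``pct / 10``).

    Raises
    ------
    RecipeColumnError, RecipeOrderError, RecipeSpacingError, RecipeRangeError
        Each names the offending row or column.
    """
    df = pd.read_csv(io.StringIO(csv_text))
    cols = set(df.columns)
    light_col = "light_v"
    if "light_v" not in cols and "light_pct" in cols:
        light_col = "light_pct"
    for name in RECIPE_COLUMNS:
        if name == "light_v":
            if light_col not in cols:
                raise RecipeColumnError("missing column light_v (or light_pct)")
            continue
        if name not in cols:
            raise RecipeColumnError(f"missing column {name}")
    rows = []
    for _, rec in df.iterrows():
        light = float(rec[light_col])
        if light_col == "light_pct":
            light = light / 10.0
        rows.append(
            SetpointRow(
                offset_s=float(rec["offset_s"]),
                temp_sp=float(rec["temp_c"]),
                rh_sp=float(rec["rh_pct"]),
                light_cmd=light,
                irrigation_s=float(rec["irrigation_s"]),
            )
        )
    return Recipe(rows=tuple(rows), recipe_id=recipe_id, version=version)


def write_recipe(recipe: Recipe) -> str:
    """Serialise a recipe back to the canonical CSV dialect."""
    df = pd.DataFrame(
        {
            "offset_s": [r.offset_s for r in recipe.rows],
            "temp_c": [r.temp_sp for r in recipe.rows],
            "rh_pct": [r.rh_sp for r in recipe.rows],
            "light_v": [r.light_cmd for r in recipe.rows],
            "irrigation_s": [r.irrigation_s for r in recipe.rows],
        }
    )
    return df.to_csv(index=False)


def active_setpoint(recipe: Recipe, t: float) -> SetpointRow:
    """Return the setpoint in force at time ``t`` (seconds).

    Step-hold semantics: the last row with ``offset_s <= t`` applies, so
    each row governs the left-closed interval up to the next row, and the
    final row holds indefinitely.
    """
    if t < 0:
        raise ValueError("t must be >= 0")
    offsets = recipe.__dict__["_offsets"]
    idx = bisect_right(offsets, t) - 1
    return recipe.rows[idx]


def weather_to_recipe(
    weather: WeatherSeries,
    out_spacing_s: float,
    mode: str = "linear",
    *,
    rh_sp: float = 50.0,
    light_cmd: float = 0.0,
    recipe_id: str = "weather-replay",
) -> Recipe:
    """Convert a temperature series into a fine-grained replay recipe.

    ``linear`` interpolates between weather samples; ``hold`` repeats the
    prior sample.  Output rows run from 0 to the last weather offset at
    ``out_spacing_s``; humidity and lighting are constant fills since the
    replay protocol drives temperature only.
    """
    if out_spacing_s < MIN_ROW_SPACING_S:
        raise RecipeSpacingError(
            f"output spacing {out_spacing_s:g} s below minimum {MIN_ROW_SPACING_S:g} s"
        )
    ratio = weather.spacing_s / out_spacing_s
    if abs(ratio - round(ratio)) > 1e-9:
        raise RecipeSpacingError(
            f"output spacing {out_spacing_s:g} s does not divide weather "
            f"spacing {weather.spacing_s:g} s"
        )
    if mode not in ("hold", "linear"):
        raise ValueError(f"unknown mode {mode!r}")
    t0 = weather.offsets_s[0]
    rel = np.array(weather.offsets_s) - t0
    temps = np.array(weather.temps_c)
    out_t = np.arange(0.0, rel[-1] + out_spacing_s / 2, out_spacing_s)
    if mode == "linear":
        out_temp = np.interp(out_t, rel, temps)
    else:
        idx = np.searchsorted(rel, out_t, side="right") - 1
        out_temp = temps[idx]
    rows = tuple(
        SetpointRow(float(t), float(tc), rh_sp, light_cmd, 0.0)
        for t, tc in zip(out_t, out_temp)
    )
    return Recipe(rows=rows, recipe_id=recipe_id)


def generate_synthetic_weather(
    days: int,
    t_min: float,
    t_max: float,
    spacing_s: float = 1800.0,
    seed: int = 0,
    noise_sd: float = 0.0,
) -> WeatherSeries:
    """Generate a diurnal temperature series standing in for station data.

    The noiseless signal is a 24 h sinusoid whose minimum and maximum equal
    ``t_min`` and ``t_max``, with the minimum at 05:00 and the maximum at
    17:00 local time (typical land-surface phasing).  Gaussian noise of
    ``noise_sd`` °C is added per sample and the result clipped back to
    ``[t_min, t_max]``.  Identical seeds give bitwise-identical series.
    """
    if t_min >= t_max:
        raise ValueError("t_min must be strictly below t_max")
    if days < 1:
        raise ValueError("days must be >= 1")
    if spacing_s <= 0:
        raise ValueError("spacing_s must be positive")
    n = int(round(days * 86400.0 / spacing_s))
    t = np.arange(n) * spacing_s
    mid = (t_min + t_max) / 2.0
    amp = (t_max - t_min) / 2.0
    # Minimum at 05:00: phase shift of 18000 s on the -cos carrier.
    temps = mid - amp * np.cos(2 * np.pi * (t - 18000.0) / 86400.0)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        temps = temps + rng.normal(0.0, noise_sd, size=n)
    temps = np.clip(temps, t_min, t_max)
    return WeatherSeries(
        offsets_s=tuple(float(x) for x in t),
        temps_c=tuple(float(x) for x in temps),
        spacing_s=float(spacing_s),
    )


def parse_weather(csv_text: str) -> WeatherSeries:
    """Read a weather CSV with header ``offset_s,temp_c``."""
    df = pd.read_csv(io.StringIO(csv_text))
    for name in ("offset_s", "temp_c"):
        if name not in df.columns:
            raise RecipeColumnError(f"missing column {name}")
    offsets = [float(x) for x in df["offset_s"]]
    if len(offsets) < 2:
        raise ValueError("weather series needs at least 2 samples")
    spacing = offsets[1] - offsets[0]
    return WeatherSeries(
        offsets_s=tuple(offsets),
        temps_c=tuple(float(x) for x in df["temp_c"]),
        spacing_s=spacing,
    )


def write_weather(weather: WeatherSeries) -> str:
    df = pd.DataFrame({"offset_s": weather.offsets_s, "temp_c": weather.temps_c})
    return df.to_csv(index=False)
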