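import pytest

from growcab.cabinet import Mode, PlantParams
from growcab.mpc import MODE_PRIORITY
from growcab.recipes import Recipe, SetpointRow, generate_synthetic_weather, weather_to_recipe


def brute_force_select(state, setpoint, rates, config, history):
    """Independent re-enumeration of the controller's mode-selection rule.

    Used as the oracle against :func:`growcab.mpc.select_action`; kept
    deliberately naive (explicit loops, no shared helpers).
    """
    err = state.temp - setpoint
    if history.mode in (Mode.HEAT, Mode.COOL) and abs(err) <= config.early_stop_band:
        return Mode.FAN
    if state.t - history.since_s < config.min_mode_s:
        return history.mode
    fastest = max(abs(rates.rates[Mode.COOL]), abs(rates.rates[Mode.HEAT]), 1e-6)
    horizon = min(max(abs(err) / fastest * 60.0, config.horizon_min_s),
                  config.horizon_max_s)
    n = max(1, int(horizon // config.cycle_s))
    best_mode, best_key = None, None
    for m in (Mode.FAN, Mode.IDLE, Mode.HEAT, Mode.COOL):
        if m is Mode.COOL and state.t - history.last_heat_s < config.stabilize_s:
            continue
        if m is Mode.HEAT and state.t - history.last_cool_s < config.stabilize_s:
            continue
        j = 0.0
        for i in range(1, n + 1):
            pred = state.temp + rates.rates[m] * (i * config.cycle_s) / 60.0
            j += config.w1 * (pred - setpoint) ** 2
        if m is not history.mode:
            j += config.w2
        key = (j, MODE_PRIORITY[m])
        if best_key is None or key < best_key:
            best_mode, best_key = m, key
    return best_mode


@pytest.fixture
def constant_recipe() -> Recipe:
    """Single-row recipe holding 23 °C / 60 % RH with lights off."""
    return Recipe(rows=(SetpointRow(0.0, 23.0, 60.0, 0.0, 0.0),))


@pytest.fixture
def step_recipe() -> Recipe:
    """Two-segment recipe stepping 23 → 25 °C at t = 60 s."""
    return Recipe(
        rows=(
            SetpointRow(0.0, 23.0, 60.0, 0.0, 0.0),
            SetpointRow(60.0, 25.0, 60.0, 0.0, 0.0),
        )
    )


@pytest.fixture
def quiet_plant() -> PlantParams:
    """Default-calibrated plant with sensor noise disabled."""
    return PlantParams(noise_sd=0.0)


@pytest.fixture(scope="session")
def diurnal_recipe() -> Recipe:
    """48 h replay recipe from the synthetic 15.3–30.3 °C diurnal series."""
    weather = generate_synthetic_weather(2, 15.3, 30.3, 1800.0, seed=7)
    return weather_to_recipe(weather, 30.0, "linear")
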