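"""Adaptive MPC: rate learning, cost, mode selection, closed loop."""

import math
import random

import numpy as np
import pytest

from growcab.cabinet import Mode, PlantParams, ThermalState
from growcab.mpc import (
    MODE_PRIORITY,
    THERMAL_CANDIDATES,
    ClosedLoopTrace,
    ControllerConfig,
    HumidityCommand,
    ModeHistory,
    RateTable,
    action_cost,
    control_humidity,
    predict_temperature,
    run_closed_loop,
    select_action,
    update_rate,
)
from growcab.recipes import Recipe, SetpointRow


class TestUpdateRate:
    def test_fixed_point(self):
        assert update_rate(0.30, 0.30, 0.1) == pytest.approx(0.30)

    def test_alpha_one_full_replacement(self):
        assert update_rate(-3.7, 0.5, 1.0) == 0.5

    def test_ema_arithmetic(self):
        assert update_rate(0.20, 0.30, 0.1) == pytest.approx(0.21)

    @pytest.mark.parametrize("alpha", [0.0, -0.1, 1.5])
    def test_alpha_bounds(self, alpha):
        with pytest.raises(ValueError):
            update_rate(0.1, 0.2, alpha)

    def test_contraction_closed_form(self):
        """n identical observations shrink the error by (1 - α)^n exactly."""
        alpha, r_obs, rate = 0.1, -0.25, 0.4
        err0 = abs(rate - r_obs)
        for n in range(1, 50):
            rate = update_rate(rate, r_obs, alpha)
            assert abs(rate - r_obs) == pytest.approx(err0 * (1 - alpha) ** n)

    def test_learned_rate_stays_in_observed_envelope(self):
        rng = random.Random(3)
        obs = [rng.uniform(-0.5, 0.5) for _ in range(200)]
        rate = obs[0]
        for o in obs[1:]:
            rate = update_rate(rate, o, 0.1)
            assert min(obs) - 1e-12 <= rate <= max(obs) + 1e-12


class TestPredictAndCost:
    def test_zero_rate_identity(self):
        assert predict_temperature(25.0, 0.0, 600.0) == 25.0

    def test_linear_forecast(self):
        assert predict_temperature(25.0, -0.246, 60.0) == pytest.approx(24.754)

    def test_zero_dt(self):
        assert predict_temperature(25.0, 1.0, 0.0) == 25.0

    def test_perfect_tracking_zero_cost(self):
        assert action_cost([23.0, 23.0], 23.0, 0.0) == 0.0

    def test_single_step_unit_error(self):
        assert action_cost([24.0], 23.0, 0.0, w1=1.0, w2=0.0) == pytest.approx(1.0)

    def test_switch_penalty_added_once(self):
        base = action_cost([24.0, 25.0], 23.0, 0.0, w1=1.0, w2=0.7)
        assert action_cost([24.0, 25.0], 23.0, 1.0, w1=1.0, w2=0.7) == pytest.approx(
            base + 0.7
        )

    def test_empty_prediction_rejected(self):
        with pytest.raises(ValueError):
            action_cost([], 23.0, 0.0)


from conftest import brute_force_select as oracle_select


class TestSelectAction:
    def default(self):
        return ControllerConfig()

    def test_hot_cabinet_selects_cool(self):
        rates = RateTable(
            rates={Mode.COOL: -0.5, Mode.HEAT: 0.5, Mode.FAN: 0.05,
                   Mode.IDLE: 0.05, Mode.DRY: 0.0}
        )
        config = ControllerConfig(w2=0.0)
        d = select_action(
            ThermalState(1000.0, 28.0), 23.0, rates, config,
            ModeHistory(Mode.FAN, since_s=0.0),
        )
        assert d.mode is Mode.COOL
        assert d.costs[Mode.COOL] == min(d.costs.values())

    def test_early_termination_returns_fan(self):
        d = select_action(
            ThermalState(500.0, 23.2), 23.0, RateTable(), self.default(),
            ModeHistory(Mode.COOL, since_s=480.0),
        )
        assert d.mode is Mode.FAN
        assert d.early_termination

    def test_at_setpoint_fan_by_tiebreak(self):
        rates = RateTable(
            rates={m: 0.0 for m in Mode} | {Mode.COOL: -0.3, Mode.HEAT: 0.3}
        )
        d = select_action(
            ThermalState(1000.0, 23.0), 23.0, rates, ControllerConfig(w2=0.0),
            ModeHistory(Mode.IDLE, since_s=0.0),
        )
        assert d.mode is Mode.FAN

    def test_min_mode_time_pins_current_mode(self):
        d = select_action(
            ThermalState(30.0, 28.0), 23.0, RateTable(), self.default(),
            ModeHistory(Mode.HEAT, since_s=0.0),
        )
        assert d.mode is Mode.HEAT  # stuck despite COOL being better

    def test_stabilize_lockout_blocks_reversal(self):
        history = ModeHistory(Mode.FAN, since_s=200.0, last_heat_s=250.0)
        d = select_action(
            ThermalState(300.0, 28.0), 23.0, RateTable(), self.default(), history
        )
        assert d.mode is not Mode.COOL

    def test_oracle_equivalence_on_random_instances(self):
        """select_action matches brute-force enumeration on 1000 cases."""
        rng = random.Random(12345)
        for _ in range(1000):
            t = rng.uniform(0, 5000)
            state = ThermalState(t, rng.uniform(10, 40))
            setpoint = rng.uniform(12, 38)
            rates = RateTable(
                rates={
                    Mode.COOL: rng.uniform(-0.6, -0.01),
                    Mode.HEAT: rng.uniform(0.01, 0.6),
                    Mode.FAN: rng.uniform(-0.05, 0.05),
                    Mode.IDLE: rng.uniform(-0.05, 0.05),
                    Mode.DRY: 0.0,
                }
            )
            config = ControllerConfig(
                cycle_s=10.0,
                w1=rng.uniform(0.5, 2.0),
                w2=rng.uniform(0.0, 0.5),
                min_mode_s=rng.choice([0.0, 60.0]),
                stabilize_s=rng.choice([0.0, 120.0]),
            )
            mode = rng.choice(list(THERMAL_CANDIDATES))
            history = ModeHistory(
                mode=mode,
                since_s=t - rng.uniform(0, 300),
                last_heat_s=t - rng.uniform(0, 400),
                last_cool_s=t - rng.uniform(0, 400),
            )
            expected = oracle_select(state, setpoint, rates, config, history)
            got = select_action(state, setpoint, rates, config, history)
            assert got.mode is expected


class TestControlHumidity:
    @pytest.mark.parametrize(
        "rh,sp,cmd",
        [
            (60.0, 60.0, HumidityCommand.HOLD),
            (54.0, 60.0, HumidityCommand.HUMIDIFY),
            (66.0, 60.0, HumidityCommand.DRY),
            (55.0, 60.0, HumidityCommand.HOLD),  # on the band edge: hold
        ],
    )
    def test_hysteresis(self, rh, sp, cmd):
        assert control_humidity(rh, sp, band=5.0) is cmd

    def test_invalid_rh_rejected(self):
        with pytest.raises(ValueError):
            control_humidity(120.0, 60.0)


class TestClosedLoop:
    def test_equilibrium_stays_passive_and_flat(self, constant_recipe):
        plant = PlantParams(noise_sd=0.0, k_leak=0.0)
        trace = run_closed_loop(constant_recipe, plant, duration_s=1800.0, seed=0)
        assert len(trace) == 180
        assert all(m in (Mode.FAN, Mode.IDLE) for m in trace.mode)
        assert all(t == pytest.approx(23.0) for t in trace.temp_c)

    def test_trace_length_and_determinism(self, constant_recipe):
        plant = PlantParams()
        a = run_closed_loop(constant_recipe, plant, duration_s=3600.0, seed=9)
        b = run_closed_loop(constant_recipe, plant, duration_s=3600.0, seed=9)
        assert len(a) == 360
        assert a.temp_c == b.temp_c and a.mode == b.mode

    def test_learned_cool_rate_recovers_true_plant_rate(self, constant_recipe):
        """30 min of forced cooling learns a −0.25 °C·min⁻¹ plant within 10 %."""
        # Nearly constant-rate plant: distant cold target, small gain.
        plant = PlantParams(
            k_cool=0.25 / 1025.0, T_cool_target=-1000.0, k_leak=0.0, noise_sd=0.0
        )
        rates = RateTable()
        config = ControllerConfig()
        rng = np.random.default_rng(0)
        state = ThermalState(0.0, 25.0)
        from growcab.cabinet import step_plant

        for _ in range(180):  # 30 min at 10 s cycles
            new = step_plant(state, Mode.COOL, config.cycle_s, plant, rng)
            observed = (new.temp - state.temp) / (config.cycle_s / 60.0)
            rates.update(Mode.COOL, observed)
            state = new
        assert rates.rates[Mode.COOL] == pytest.approx(-0.25, rel=0.10)

    def test_lockout_and_min_on_time_contracts_over_trace(self, diurnal_recipe):
        """No heat/cool reversal within stabilize_s; no early mode exit."""
        config = ControllerConfig()
        trace = run_closed_loop(
            diurnal_recipe, PlantParams(), config, duration_s=6 * 3600.0, seed=3
        )
        modes, times = trace.mode, trace.t_s
        last_active_end = {Mode.HEAT: -math.inf, Mode.COOL: -math.inf}
        entered = 0.0
        for i in range(1, len(modes)):
            prev, cur, t = modes[i - 1], modes[i], times[i]
            if prev in (Mode.HEAT, Mode.COOL):
                last_active_end[prev] = times[i - 1] + config.cycle_s
            if cur != prev:
                opposite = {Mode.HEAT: Mode.COOL, Mode.COOL: Mode.HEAT}.get(cur)
                if opposite is not None:
                    assert t - last_active_end[opposite] >= config.stabilize_s - 1e-9
                # exits before min_mode_s only via early termination to FAN
                if t - entered < config.min_mode_s:
                    assert cur is Mode.FAN and prev in (Mode.HEAT, Mode.COOL)
                entered = t

    def test_diurnal_tracking_error_bounded(self, diurnal_recipe):
        """48 h synthetic diurnal replay tracks within 1 °C MAE."""
        trace = run_closed_loop(
            diurnal_recipe, PlantParams(), duration_s=172800.0, seed=11
        )
        err = np.abs(np.array(trace.temp_c) - np.array(trace.setpoint_c))
        assert err.mean() <= 1.0
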