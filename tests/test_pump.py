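"""Pump hydraulics, motor/controller dynamics and the flow estimator."""

import numpy as np
import pytest

from suctionsim import PumpParams, PumpStallError
from suctionsim.pump import (RPM_TO_RAD, MLPS_TO_LPM, controller_step,
                             estimate_flow, head_pressure, hydraulic_torque,
                             step_motor, PumpState)


@pytest.fixture()
def params():
    return PumpParams()


class TestHeadPressure:
    def test_zero_at_rest(self, params):
        assert head_pressure(0.0, 0.0, params.hq_coeffs) == 0.0

    def test_monotone_decreasing_in_flow(self, params):
        q = np.linspace(0.0, 8.0, 81)
        head = np.array([head_pressure(qi, 2800.0, params.hq_coeffs)
                         for qi in q])
        assert np.all(np.diff(head) < 0.0)

    def test_head_matches_dcm_gradient(self, dcm_steady):
        """Closed-loop consistency: at the DCM operating point the pump head
        equals the arterial-minus-ventricular gradient plus cannula losses."""
        record, summary = dcm_steady
        params = PumpParams()
        q_mean = float(np.mean(record.q_pump))              # mL/s
        head = head_pressure(q_mean * MLPS_TO_LPM, 2800.0, params.hq_coeffs)
        gradient = float(np.mean(record.p_ao - record.p_lv))
        # difference is the mean cannula/graft resistive drop
        assert head == pytest.approx(gradient, abs=15.0)
        assert head > gradient  # the pump must overcome the graft losses


class TestController:
    def test_at_setpoint_outputs_integral_term(self, params):
        gains = params.controller_gains
        cmd, integral = controller_step(2800.0, 2800.0, 2.0, gains, 1e-3)
        assert integral == 2.0
        assert cmd == pytest.approx(gains["ki"] * 2.0)

    def test_command_increases_below_setpoint(self, params):
        gains = params.controller_gains
        low, _ = controller_step(2700.0, 2800.0, 1.0, gains, 1e-3)
        ref, _ = controller_step(2800.0, 2800.0, 1.0, gains, 1e-3)
        assert low > ref

    def test_integral_accumulates_error(self, params):
        gains = params.controller_gains
        err_rad = (2800.0 - 2750.0) * RPM_TO_RAD
        _, integral = controller_step(2750.0, 2800.0, 0.0, gains, 1e-3)
        assert integral == pytest.approx(err_rad * 1e-3)

    def test_anti_windup_clamps(self, params):
        gains = dict(params.controller_gains, i_max=0.5)
        integral = 0.0
        for _ in range(2000):
            cmd, integral = controller_step(2000.0, 2800.0, integral,
                                            gains, 1e-3)
        assert cmd == 0.5
        # integral held near the clamp, not unbounded
        assert gains["ki"] * integral < 5.0


class TestMotor:
    def test_equilibrium_speed_constant(self, params):
        omega = params.speed_setpoint
        state = PumpState(omega=omega, integral=0.0)
        # command at zero integral, then choose a load that matches it
        cmd, _ = controller_step(omega, params.speed_setpoint, 0.0,
                                 params.controller_gains, 1e-3)
        load = params.torque_constant * cmd \
            - params.friction_coeff * omega * RPM_TO_RAD
        new = step_motor(state, load, 1e-3, params)
        assert new.omega == pytest.approx(omega, abs=0.05)

    def test_load_step_dips_then_recovers(self, params):
        omega_rad = params.speed_setpoint * RPM_TO_RAD
        base_load = 60.0 * omega_rad * params.flow_torque_coeff
        state = PumpState(omega=params.speed_setpoint,
                          integral=base_load / (params.torque_constant
                                                * params.controller_gains["ki"]))
        trace = []
        for i in range(4000):
            load = base_load * (2.0 if i >= 100 else 1.0)
            state = step_motor(state, load, 1e-3, params)
            trace.append(state.omega)
        trace = np.array(trace)
        assert trace[100:1500].min() < params.speed_setpoint - 5.0  # dip
        assert trace[-1] == pytest.approx(params.speed_setpoint, abs=5.0)

    def test_stall_raises(self, params):
        state = PumpState(omega=1.0, integral=0.0)
        with pytest.raises(PumpStallError):
            for _ in range(100):
                state = step_motor(state, 1.0, 1e-3, params)

    def test_dt_bound(self, params):
        with pytest.raises(ValueError):
            step_motor(PumpState(omega=2800.0), 0.0, 5e-3, params)


class TestEstimator:
    def test_inverts_torque_balance(self, params):
        # current consistent with a known flow maps back to that flow
        q_mlps, omega = 75.0, 2800.0
        omega_rad = omega * RPM_TO_RAD
        i_motor = (hydraulic_torque(q_mlps, omega_rad, params)
                   + params.friction_coeff * omega_rad) \
            / params.torque_constant
        q_est = estimate_flow(i_motor, omega, params.estimator_coeffs)
        assert q_est == pytest.approx(q_mlps * MLPS_TO_LPM, rel=1e-9)

    def test_requires_positive_speed(self, params):
        with pytest.raises(ValueError):
            estimate_flow(0.5, 0.0, params.estimator_coeffs)

    def test_beat_mean_estimate_tracks_true_flow(self, dcm_steady):
        """Non-suction steady state: reported flow within 10% of true flow."""
        record, summary = dcm_steady
        assert abs(np.mean(record.q_est)
                   - summary.pump_flow_mean) / summary.pump_flow_mean < 0.10

    def test_power_nonnegative(self, dcm_steady):
        record, _ = dcm_steady
        assert np.all(record.power >= 0.0)
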