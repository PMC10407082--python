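"""Continuous-flow rotary pump: hydraulics, motor, speed controller, estimator.

The hydraulic characteristic is the standard quadratic head map
ΔP = a0·ω² + a1·ω·q + a2·q² (ω in rpm, q in L/min, ΔP in mmHg), fit to be
HVAD-like: flat over the operating range, with the head at 2,800 rpm and the
dilated-cardiomyopathy operating point matching the arterial-minus-ventricular
gradient of that profile's steady state.

The impeller obeys J·dω/dt = k_t·I − T_hydraulic − T_friction with
T_hydraulic = c_q·q·ω.  A PI controller holds the speed at its setpoint; the
intra-beat speed excursion this leaves (~±50 rpm without suction, ~+100 rpm
during a collapse) is the dynamic signature the detection features key on.
The on-device flow estimator inverts the torque balance from measured current
and speed, mimicking how clinical devices report an *estimated* flow channel.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .config import PumpParams

RPM_TO_RAD = 2.0 * math.pi / 60.0
MLPS_TO_LPM = 0.06


class PumpStallError(RuntimeError):
    """Raised when impeller speed collapses to zero during operation."""


@dataclass
class PumpState:
    """Instantaneous pump/motor state."""

    omega: float                # impeller speed [rpm]
    q_pump: float = 0.0         # instantaneous pump flow [mL/s]
    i_motor: float = 0.0        # motor current [A]
    integral: float = 0.0       # controller integral state [rad/s * s]
    power: float = 0.0          # electrical shaft power [W]
    q_est: float = 0.0          # estimated pump flow [L/min]


def head_pressure(q_lpm: float, omega_rpm: float, coeffs) -> float:
    """Differential pressure across the pump [mmHg].

    Quadratic in speed and flow; monotone decreasing in flow over the
    operating range for the shipped coefficients.
    """
    a0, a1, a2 = coeffs
    return a0 * omega_rpm * omega_rpm + a1 * omega_rpm * q_lpm \
        + a2 * q_lpm * q_lpm


def hydraulic_torque(q_mlps: float, omega_rad: float, params: PumpParams) -> float:
    """Load torque on the impeller from the pumped fluid [N m]."""
    return params.flow_torque_coeff * q_mlps * omega_rad


def controller_step(omega_rpm: float, setpoint_rpm: float,
                    integral_state: float, gains: dict, dt: float
                    ) -> tuple[float, float]:
    """One discrete PI update: returns (current command [A], new integral).

    Anti-windup: the integral only accumulates while the command is not
    saturated against the limit it would push further into.
    """
    err = (setpoint_rpm - omega_rpm) * RPM_TO_RAD
    kp, ki = gains["kp"], gains["ki"]
    i_max = gains.get("i_max", 3.0)
    raw = kp * err + ki * (integral_state + err * dt)
    if (raw > i_max and err > 0.0) or (raw < 0.0 and err < 0.0):
        new_integral = integral_state          # hold: anti-windup clamp
    else:
        new_integral = integral_state + err * dt
    cmd = kp * err + ki * new_integral
    return min(max(cmd, 0.0), i_max), new_integral


def step_motor(state: PumpState, load_torque: float, dt: float,
               params: PumpParams) -> PumpState:
    """Advance the impeller/motor dynamics by ``dt`` (explicit Euler).

    The current is set by the PI speed controller; the speed responds to the
    imbalance between motor and load torque.
    """
    if dt > 1.0e-3:
        raise ValueError(f"dt must be <= 1 ms, got {dt}")
    omega_rad = state.omega * RPM_TO_RAD
    i_cmd, integral = controller_step(
        state.omega, params.speed_setpoint, state.integral,
        params.controller_gains, dt)
    torque = params.torque_constant * i_cmd - load_torque \
        - params.friction_coeff * omega_rad
    omega_rad += dt * torque / params.impeller_inertia
    if omega_rad <= 0.0:
        raise PumpStallError(
            f"impeller speed reached {omega_rad / RPM_TO_RAD:.0f} rpm "
            f"under load torque {load_torque:.2e} N m")
    return PumpState(
        omega=omega_rad / RPM_TO_RAD,
        q_pump=state.q_pump,
        i_motor=i_cmd,
        integral=integral,
        power=params.torque_constant * i_cmd * omega_rad,
        q_est=state.q_est,
    )


def estimate_flow(i_motor: float, omega_rpm: float, coeffs: dict) -> float:
    """Static flow estimate from motor current and speed [L/min].

    Inverts the torque balance k_t·I = c_q·q·ω + b·ω, the same principle
    device firmware uses.  Calibrated so beat means track the true flow in
    non-suction steady states.
    """
    if omega_rpm <= 0.0:
        raise ValueError(f"estimator needs omega > 0, got {omega_rpm}")
    omega_rad = omega_rpm * RPM_TO_RAD
    kt = coeffs["torque_constant"]
    bf = coeffs["friction_coeff"]
    cq = coeffs["flow_torque_coeff"]
    q_mlps = (kt * i_motor - bf * omega_rad) / (cq * omega_rad)
    return q_mlps * MLPS_TO_LPM
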