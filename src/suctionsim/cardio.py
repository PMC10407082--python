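"""Closed-loop lumped-parameter circulation.

Four time-varying-elastance chambers (LV, LA, RV, RA), four diode-resistance
valves and two RC vascular beds with explicit venous compartments.  Chamber
pressure blends a linear end-systolic PV relationship P_es = Ees·(V − V0)
with an exponential end-diastolic one P_ed = S·(exp(k·(V − V0)) − 1), the
stiffness k anchored so that P_ed(V30) = 30 mmHg.  The blend weight is a
periodic double-Hill activation normalized to peak at exactly 1.

Total blood volume is conserved by construction: every flow leaves one
compartment and enters another, and the pump withdrawal from the LV apex
re-enters at the systemic arterial node.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .config import PatientProfile

logger = logging.getLogger(__name__)

#: chamber pressures are clamped above this floor to keep the solver stable
#: before the collapse dynamics of the suction module engage
PRESSURE_FLOOR = -20.0


# ---------------------------------------------------------------------------
# activation
# ---------------------------------------------------------------------------

@dataclass
class ActivationShape:
    """Double-Hill activation waveform, defined on normalized phase."""

    m1: float = 1.9
    m2: float = 21.9
    tau1_frac: float = 0.215
    tau2_frac: float = 0.33
    _norm: float = field(default=0.0, repr=False)

    def __post_init__(self) -> None:
        phi = np.linspace(0.0, 1.0, 4001)
        self._norm = float(np.max(self._raw(phi)))

    def _raw(self, phi):
        g1 = (phi / self.tau1_frac) ** self.m1
        g2 = (phi / self.tau2_frac) ** self.m2
        return (g1 / (1.0 + g1)) / (1.0 + g2)

    def __call__(self, phi: float) -> float:
        g1 = (phi / self.tau1_frac) ** self.m1
        g2 = (phi / self.tau2_frac) ** self.m2
        return (g1 / (1.0 + g1)) / (1.0 + g2) / self._norm


def activation(t_in_cycle: float, hr: float,
               shape: ActivationShape | None = None) -> float:
    """Normalized activation level in [0, 1] at time ``t_in_cycle`` [s].

    Periodic with period 60/hr; zero at end-diastole (cycle start) and
    reaching 1 exactly once per cycle.
    """
    if hr <= 0:
        raise ValueError(f"heart rate must be positive, got {hr}")
    shape = shape or ActivationShape()
    period = 60.0 / hr
    phi = (t_in_cycle % period) / period
    return shape(phi)


# ---------------------------------------------------------------------------
# chambers and valves
# ---------------------------------------------------------------------------

@dataclass
class ChamberParams:
    """Elastance-chamber constants.

    Ventricles (``kind='ventricle'``) use the exponential EDPVR with scale
    ``passive_scale`` (S) and stiffness solved from the V30 anchor:
    k = ln(1 + 30/S) / (V30 − V0).  Atria use a linear elastance swinging
    between ``e_min`` and ``e_max`` with activation.
    """

    e_max: float
    v0: float
    kind: str = "ventricle"
    passive_scale: float = 0.05
    v30: float | None = None
    v0_ed: float | None = None  # EDPVR zero-pressure volume (defaults to v0)
    #: low-volume saturation of the ESPVR: systolic pressure scales with
    #: V/(V + v_sat), so an emptying ventricle loses its pressure-generating
    #: capacity (curvilinear ESPVR; the local slope near the operating range
    #: still equals e_max).  0 disables the saturation (pure linear ESPVR).
    es_saturation_volume: float = 0.0
    e_min: float = 0.1          # atrial passive elastance [mmHg/mL]
    stiffness: float = field(default=0.0)

    def __post_init__(self) -> None:
        if self.kind == "ventricle":
            if self.v0_ed is None:
                self.v0_ed = self.v0
            if self.v30 is None:
                raise ValueError("ventricle chambers need a v30 anchor")
            if self.v30 <= self.v0_ed:
                raise ValueError(
                    f"v30 ({self.v30}) must exceed v0_ed ({self.v0_ed})")
            if self.passive_scale <= 0:
                raise ValueError("passive_scale must be > 0")
            self.stiffness = math.log(1.0 + 30.0 / self.passive_scale) \
                / (self.v30 - self.v0_ed)
        if not (self.e_max >= (self.e_min if self.kind == "atrium" else 0.0)):
            raise ValueError("e_max must be >= e_min > 0")

    def pressure(self, v: float, act: float) -> float:
        """Chamber pressure [mmHg] at volume ``v`` and activation ``act``."""
        if self.kind == "atrium":
            p = (self.e_min + act * (self.e_max - self.e_min)) * (v - self.v0)
        else:
            sat = self.es_saturation_volume
            if sat > 0.0:
                frank = v / (v + sat) if v > 0.0 else 0.0
            else:
                frank = 1.0
            p_es = self.e_max * (v - self.v0) * frank
            # exponential EDPVR, extrapolates smoothly below its intercept
            p_ed = self.passive_scale * (
                math.exp(self.stiffness * (v - self.v0_ed)) - 1.0)
            p = act * p_es + (1.0 - act) * p_ed
        if p < PRESSURE_FLOOR:
            logger.debug("chamber pressure floored at %s mmHg (v=%.1f)",
                         PRESSURE_FLOOR, v)
            return PRESSURE_FLOOR
        return p


def chamber_pressure(v: float, t_in_cycle: float, params: ChamberParams,
                     hr: float = 78.0,
                     shape: ActivationShape | None = None) -> float:
    """Time-varying-elastance chamber pressure [mmHg]."""
    return params.pressure(v, activation(t_in_cycle, hr, shape))


def valve_flow(p_up: float, p_down: float, r_valve: float) -> float:
    """Diode-resistance valve: forward flow only, (ΔP)/R when open [mL/s]."""
    dp = p_up - p_down
    return dp / r_valve if dp > 0.0 else 0.0


# ---------------------------------------------------------------------------
# circulation state + model
# ---------------------------------------------------------------------------

#: order of the eight volume states [mL]
VOLUME_NAMES = ("v_lv", "v_la", "v_rv", "v_ra", "v_sa", "v_sv", "v_pa", "v_pv")


@dataclass
class CirculationState:
    """Instantaneous volumes [mL] plus derived pressures/flows of interest."""

    volumes: np.ndarray
    pressures: dict = field(default_factory=dict)
    flows: dict = field(default_factory=dict)

    @property
    def total_volume(self) -> float:
        return float(np.sum(self.volumes))


class CirculationModel:
    """Evaluates pressures and volume derivatives for one patient profile."""

    def __init__(self, profile: PatientProfile):
        self.profile = profile
        self.hr = profile.hr
        self.period = 60.0 / profile.hr
        act = profile.activation
        self.v_shape = ActivationShape(
            m1=act["m1"], m2=act["m2"],
            tau1_frac=act["tau1_frac"], tau2_frac=act["tau2_frac"])
        self.a_shape = ActivationShape(
            m1=act["m1"], m2=act["m2"],
            tau1_frac=act["atrial_tau1_frac"],
            tau2_frac=act["atrial_tau2_frac"])
        self.atrial_delay = act["atrial_delay_frac"] * self.period

        sat = profile.es_saturation_volume
        self.lv = ChamberParams(
            e_max=profile.ees_lv, v0=profile.v0_lv,
            passive_scale=profile.passive_scale_lv, v30=profile.v30,
            v0_ed=profile.v0_ed_lv, es_saturation_volume=sat)
        rv = profile.rv_params
        self.rv = ChamberParams(
            e_max=rv["e_max"], v0=rv["v0"],
            passive_scale=rv["passive_scale"], v30=rv["v30"],
            es_saturation_volume=sat)
        la, ra = profile.atrial_params["la"], profile.atrial_params["ra"]
        self.la = ChamberParams(e_max=la["e_max"], e_min=la["e_min"],
                                v0=la["v0"], kind="atrium")
        self.ra = ChamberParams(e_max=ra["e_max"], e_min=ra["e_min"],
                                v0=ra["v0"], kind="atrium")

        sy, pu, va = profile.systemic, profile.pulmonary, profile.valves
        self.r_sys = sy["resistance"]
        self.c_sa = sy["compliance"]
        self.r_sv = sy["venous_resistance"]
        self.c_sv = sy["venous_compliance"]
        self.v0_sa = sy["arterial_unstressed"]
        self.v0_sv = sy["venous_unstressed"]
        self.r_pul = pu["resistance"]
        self.c_pa = pu["compliance"]
        self.r_pv = pu["venous_resistance"]
        self.c_pv = pu["venous_compliance"]
        self.v0_pa = pu["arterial_unstressed"]
        self.v0_pv = pu["venous_unstressed"]
        self.r_mv, self.r_av = va["r_mv"], va["r_av"]
        self.r_tv, self.r_pvalve = va["r_tv"], va["r_pv"]

    # -- pressures ----------------------------------------------------------

    def activations(self, t: float) -> tuple[float, float]:
        phi_v = (t % self.period) / self.period
        phi_a = ((t + self.period - self.atrial_delay) % self.period) \
            / self.period
        return self.v_shape(phi_v), self.a_shape(phi_a)

    def pressures(self, volumes, t: float) -> tuple:
        """(P_lv, P_la, P_rv, P_ra, P_sa, P_sv, P_pa, P_pv) at time t [mmHg]."""
        a_v, a_a = self.activations(t)
        v_lv, v_la, v_rv, v_ra, v_sa, v_sv, v_pa, v_pv = volumes
        return (
            self.lv.pressure(v_lv, a_v),
            self.la.pressure(v_la, a_a),
            self.rv.pressure(v_rv, a_v),
            self.ra.pressure(v_ra, a_a),
            (v_sa - self.v0_sa) / self.c_sa,
            (v_sv - self.v0_sv) / self.c_sv,
            (v_pa - self.v0_pa) / self.c_pa,
            (v_pv - self.v0_pv) / self.c_pv,
        )

    # -- derivatives --------------------------------------------------------

    def derivatives(self, volumes, t: float,
                    q_lv_out: float = 0.0, q_ao_in: float = 0.0):
        """Volume derivatives [mL/s] with pump withdrawal/return terms.

        ``q_lv_out`` is the apex withdrawal by the pump, ``q_ao_in`` the
        return into the systemic arterial node.  Returns ``(dv, pressures,
        flows)``; the eight volume derivatives always sum to
        ``q_ao_in − q_lv_out`` (zero for a closed pump loop), so total blood
        volume is conserved.
        """
        if not np.all(np.isfinite(volumes)):
            raise FloatingPointError(
                f"non-finite circulation state at t={t}: {volumes}")
        p = self.pressures(volumes, t)
        p_lv, p_la, p_rv, p_ra, p_sa, p_sv, p_pa, p_pv = p

        q_mv = valve_flow(p_la, p_lv, self.r_mv)
        q_av = valve_flow(p_lv, p_sa, self.r_av)
        q_tv = valve_flow(p_ra, p_rv, self.r_tv)
        q_pvalve = valve_flow(p_rv, p_pa, self.r_pvalve)
        q_sys = (p_sa - p_sv) / self.r_sys
        q_vr = (p_sv - p_ra) / self.r_sv
        q_pul = (p_pa - p_pv) / self.r_pul
        q_pvr = (p_pv - p_la) / self.r_pv

        dv = (
            q_mv - q_av - q_lv_out,          # LV
            q_pvr - q_mv,                    # LA
            q_tv - q_pvalve,                 # RV
            q_vr - q_tv,                     # RA
            q_av + q_ao_in - q_sys,          # systemic arterial
            q_sys - q_vr,                    # systemic venous
            q_pvalve - q_pul,                # pulmonary arterial
            q_pul - q_pvr,                   # pulmonary venous
        )
        flows = {"q_mv": q_mv, "q_av": q_av, "q_tv": q_tv,
                 "q_pvalve": q_pvalve, "q_sys": q_sys, "q_vr": q_vr,
                 "q_pul": q_pul, "q_pvr": q_pvr}
        return dv, p, flows

    # -- initial conditions -------------------------------------------------

    def initial_volumes(self) -> np.ndarray:
        """Physiologic starting volumes consistent with total blood volume."""
        tgt = self.profile.target_hemodynamics
        p_sa = tgt.get("sap_mean", 85.0)
        p_pa = tgt.get("pap_mean", 20.0)
        p_la = tgt.get("pcwp", 10.0)
        p_ra = 6.0
        v_lv = tgt.get("edv", 0.75 * self.profile.v30)
        v_la = self.la.v0 + p_la / self.la.e_min
        v_ra = self.ra.v0 + p_ra / self.ra.e_min
        v_rv = self.rv.v0 + 0.8 * (self.rv.v30 - self.rv.v0)
        v_sa = self.v0_sa + self.c_sa * p_sa
        v_pa = self.v0_pa + self.c_pa * p_pa
        v_pv = self.v0_pv + self.c_pv * (p_la + 2.0)
        v_sv = self.profile.total_blood_volume - (
            v_lv + v_la + v_rv + v_ra + v_sa + v_pa + v_pv)
        if v_sv <= self.v0_sv * 0.5:
            raise ValueError(
                "total_blood_volume too small for the configured unstressed "
                f"volumes (residual venous volume {v_sv:.0f} mL)")
        return np.array([v_lv, v_la, v_rv, v_ra, v_sa, v_sv, v_pa, v_pv])
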