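"""Collapsible-apex suction module.

In-silico twin of a compliant tube at the ventricular apex feeding the pump
inflow cannula.  When ventricular pressure drops below the collapse threshold
(0 mmHg) the tube is squeezed shut: the collapse fraction relaxes toward a
sigmoid of the ventricular pressure, and the inflow resistance blends from
``r_open`` (open tube) to ``r_collapsed`` (occluded).  Engagement is fast,
release slower, so a single collapse event spans the end-systolic window.

The module also emits the ground-truth suction flag used as the reference
label for the detection pipeline: a beat is a suction beat iff the collapse
fraction exceeded its threshold (default 0.5, the open/collapsed midpoint)
at any sample in the beat window.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .config import SuctionParams


@dataclass
class ApexState:
    """Collapse state of the apex tube."""

    collapse_fraction: float = 0.0    # 0 = fully open, 1 = fully collapsed
    r_inflow: float = 0.0             # current inflow resistance [mmHg s/mL]
    p_apex: float = 0.0               # pressure at the cannula inlet [mmHg]
    latched: bool = False             # squeeze actuation engaged (hysteretic)


def collapse_target(p_lv: float, params: SuctionParams) -> float:
    """Equilibrium collapse fraction for a held ventricular pressure.

    Sigmoid centered at the collapse threshold: 0.5 exactly at threshold,
    → 1 for strongly negative pressures, → 0 for positive ones.
    """
    x = params.collapse_steepness * \
        (p_lv - params.collapse_threshold_pressure)
    # guard exp overflow for very negative pressures
    if x < -40.0:
        return 1.0
    if x > 40.0:
        return 0.0
    return 1.0 / (1.0 + math.exp(x))


def inflow_resistance(collapse_fraction: float, params: SuctionParams) -> float:
    """Inflow resistance interpolated between open and collapsed limits."""
    return params.r_open + collapse_fraction * \
        (params.r_collapsed - params.r_open)


def update_latch(p_lv: float, latched: bool, params: SuctionParams) -> bool:
    """Hysteretic squeeze actuation (Schmitt trigger on chamber pressure).

    Engages when pressure crosses below the collapse threshold; releases only
    once pressure recovers above threshold + latch_release_band, so a single
    crossing commits to one full collapse event rather than dithering at the
    threshold.
    """
    thr = params.collapse_threshold_pressure
    if p_lv < thr:
        return True
    if p_lv > thr + params.latch_release_band:
        return False
    return latched


def collapse_rate(p_lv: float, collapse_fraction: float,
                  params: SuctionParams, latched: bool = False) -> float:
    """d(collapse fraction)/dt toward the sigmoid (or latched) target."""
    target = collapse_target(p_lv, params)
    if latched:
        target = 1.0
    tau = params.recovery_time_constant
    if target < collapse_fraction:          # re-opening is slower
        tau *= params.release_factor
    return (target - collapse_fraction) / tau


def collapse_dynamics(p_lv: float, state: ApexState, params: SuctionParams,
                      dt: float) -> ApexState:
    """Advance the collapse state by ``dt`` (explicit Euler)."""
    if dt > 1.0e-3:
        raise ValueError(f"dt must be <= 1 ms, got {dt}")
    latched = update_latch(p_lv, state.latched, params)
    c = state.collapse_fraction + dt * collapse_rate(
        p_lv, state.collapse_fraction, params, latched)
    c = min(max(c, 0.0), 1.0)
    return ApexState(collapse_fraction=c,
                     r_inflow=inflow_resistance(c, params),
                     p_apex=state.p_apex,
                     latched=latched)


def apex_pressure(p_lv: float, q_pump: float, state: ApexState) -> float:
    """Pressure at the cannula inlet: P_apex = P_lv − R_inflow·q_pump [mmHg].

    With the tube open and moderate pump draw, P_apex tracks P_lv; during a
    collapse with continued draw it develops the characteristic end-systolic
    negative spike.
    """
    return p_lv - state.r_inflow * q_pump


def suction_ground_truth(collapse_samples, p_lv_samples=None,
                         threshold: float = 0.5) -> bool:
    """Reference suction label for one beat window.

    TRUE iff the collapse fraction exceeded ``threshold`` at any sample in
    the window (the tube engaged while ventricular pressure crossed below the
    collapse threshold).
    """
    collapse_samples = np.asarray(collapse_samples, dtype=float)
    if collapse_samples.size == 0:
        raise ValueError("suction_ground_truth needs a non-empty beat window")
    return bool(np.any(collapse_samples > threshold))
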