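"""Patient profiles, pump/suction parameters and experiment protocols.

All quantities use the internal unit system mmHg / mL / s; pump speed is kept
in rpm and converted to rad/s only inside torque computations.  Configurations
are plain YAML (JSON is a subset and parses too) so protocols stay
human-editable.
"""

from __future__ import annotations

import copy
import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml


class ConfigurationError(ValueError):
    """A required configuration field is missing or unparseable."""


class ValidationError(ValueError):
    """A configuration value violates a model invariant."""


def _require(mapping: dict, key: str, where: str) -> Any:
    if key not in mapping:
        raise ConfigurationError(f"missing required field '{key}' in {where}")
    return mapping[key]


def _check(cond: bool, msg: str) -> None:
    if not cond:
        raise ValidationError(msg)


# ---------------------------------------------------------------------------
# patient profile
# ---------------------------------------------------------------------------

#: default double-Hill activation timing (fractions of the cardiac period)
DEFAULT_ACTIVATION = {
    "m1": 1.9,
    "m2": 21.9,
    "tau1_frac": 0.215,
    "tau2_frac": 0.30,
    "atrial_delay_frac": 0.85,   # atrial systole late in the cycle
    "atrial_tau1_frac": 0.04,
    "atrial_tau2_frac": 0.09,
}


@dataclass
class PatientProfile:
    """Cardiac/vascular parameter set realizing one heart-failure phenotype.

    ``ees_lv`` is the slope of the end-systolic pressure-volume relationship
    (contractility); ``v30`` anchors the exponential end-diastolic PV
    relationship at 30 mmHg.  Vascular parameters the source tables do not
    print are free calibration constants; the shipped built-ins are the result
    of calibrating the closed loop against the target hemodynamics.
    """

    name: str
    hr: float                       # [bpm]
    ees_lv: float                   # [mmHg/mL]
    v0_lv: float                    # [mL]
    v30: float                      # [mL]
    passive_scale_lv: float         # EDPVR scale S [mmHg]
    rv_params: dict                 # e_max, passive_scale, v0, v30
    atrial_params: dict             # la/ra: e_max, e_min, v0
    systemic: dict                  # resistance, compliance, inertance, venous_*
    pulmonary: dict
    valves: dict                    # r_mv, r_av, r_tv, r_pv
    total_blood_volume: float       # [mL]
    v0_ed_lv: float | None = None   # EDPVR volume intercept; defaults to v0_lv
    es_saturation_volume: float = 8.0   # curvilinear-ESPVR low-volume scale
    target_hemodynamics: dict = field(default_factory=dict)
    activation: dict = field(default_factory=lambda: dict(DEFAULT_ACTIVATION))

    def __post_init__(self) -> None:
        act = dict(DEFAULT_ACTIVATION)
        act.update(self.activation or {})
        self.activation = act
        self.validate()

    def validate(self) -> None:
        _check(self.hr > 0, f"hr must be > 0, got {self.hr}")
        _check(self.ees_lv > 0, f"ees_lv must be > 0, got {self.ees_lv}")
        _check(self.v30 > (self.v0_lv if self.v0_ed_lv is None
                           else self.v0_ed_lv),
               f"v30 ({self.v30}) must exceed the EDPVR volume intercept")
        _check(self.passive_scale_lv > 0,
               f"passive_scale_lv must be > 0, got {self.passive_scale_lv}")
        _check(self.total_blood_volume > 0,
               f"total_blood_volume must be > 0, got {self.total_blood_volume}")
        tgt = self.target_hemodynamics
        if "edv" in tgt and "esv" in tgt:
            _check(tgt["edv"] > tgt["esv"] >= 0,
                   f"targets require edv > esv >= 0, got {tgt['edv']}, {tgt['esv']}")
        for key in ("resistance", "compliance"):
            _check(self.systemic[key] > 0, f"systemic {key} must be > 0")
            _check(self.pulmonary[key] > 0, f"pulmonary {key} must be > 0")


# ---------------------------------------------------------------------------
# pump parameters
# ---------------------------------------------------------------------------

@dataclass
class PumpParams:
    """HVAD-like centrifugal pump constants.

    ``hq_coeffs`` (a0, a1, a2) give the head ΔP = a0·ω² + a1·ω·q + a2·q²
    in mmHg with ω in rpm and q in L/min.  Motor/controller constants are SI
    (N·m, A, rad/s); ``flow_torque_coeff`` converts q·ω (mL/s · rad/s) to
    hydraulic torque.
    """

    speed_setpoint: float = 2800.0          # [rpm]
    hq_coeffs: tuple = (1.09e-5, -3.0e-4, -0.12)
    impeller_inertia: float = 4.0e-5        # [kg m^2]
    torque_constant: float = 0.015          # [N m / A]
    friction_coeff: float = 5.0e-6          # [N m s / rad]
    flow_torque_coeff: float = 3.6e-7       # [N m / (mL/s * rad/s)]
    controller_gains: dict = field(default_factory=lambda: {
        "kp": 0.06, "ki": 0.6, "i_max": 3.0})
    estimator_coeffs: dict = field(default_factory=dict)
    graft_resistance: float = 0.05          # outflow graft [mmHg s/mL]
    cannula_inertance: float = 0.015        # [mmHg s^2/mL]
    est_filter_cutoff_hz: float = 0.55      # device smoothing of q_est
    est_slew_down: float = 1.25             # reported-flow slew limits
    est_slew_up: float = 1.2                # [L/min per s]
    sample_rate_pump: float = 50.0          # [Hz]

    def __post_init__(self) -> None:
        self.hq_coeffs = tuple(float(c) for c in self.hq_coeffs)
        if not self.estimator_coeffs:
            # default estimator inverts the motor torque balance
            self.estimator_coeffs = {
                "torque_constant": self.torque_constant,
                "friction_coeff": self.friction_coeff,
                "flow_torque_coeff": self.flow_torque_coeff,
            }
        self.validate()

    def validate(self) -> None:
        _check(1800.0 <= self.speed_setpoint <= 4000.0,
               f"speed_setpoint must be within [1800, 4000] rpm, "
               f"got {self.speed_setpoint}")
        _check(self.sample_rate_pump == 50.0,
               f"sample_rate_pump must be 50 Hz, got {self.sample_rate_pump}")
        _check(len(self.hq_coeffs) == 3, "hq_coeffs needs three coefficients")
        _check(self.impeller_inertia > 0, "impeller_inertia must be > 0")
        for g in ("kp", "ki"):
            _check(self.controller_gains[g] > 0,
                   f"controller gain {g} must be > 0")


# ---------------------------------------------------------------------------
# suction module parameters
# ---------------------------------------------------------------------------

@dataclass
class SuctionParams:
    """Collapsible-apex (Starling-resistor like) inflow restriction.

    Collapse engages when ventricular pressure drops below
    ``collapse_threshold_pressure`` (0 mmHg); the inflow resistance blends
    between ``r_open`` and ``r_collapsed`` with the collapse fraction.
    """

    collapse_threshold_pressure: float = 0.0   # [mmHg]
    collapse_steepness: float = 40.0           # sigmoid slope [1/mmHg]
    r_open: float = 0.06                       # [mmHg s/mL]
    r_collapsed: float = 3.0                   # [mmHg s/mL]
    recovery_time_constant: float = 0.02       # engage time constant [s]
    release_factor: float = 6.0                # release tau = this x engage tau
    #: hysteresis of the squeeze actuation: once ventricular pressure crosses
    #: the collapse threshold the tube is driven fully shut and only released
    #: after pressure recovers above threshold + latch_release_band
    latch_release_band: float = 0.1            # [mmHg]
    ground_truth_threshold: float = 0.5        # collapse fraction flagging suction

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        _check(self.r_open > 0, f"r_open must be > 0, got {self.r_open}")
        _check(self.r_collapsed > self.r_open,
               f"r_collapsed ({self.r_collapsed}) must exceed "
               f"r_open ({self.r_open})")
        _check(self.collapse_steepness > 0,
               f"collapse_steepness must be > 0, got {self.collapse_steepness}")
        _check(self.recovery_time_constant > 0,
               "recovery_time_constant must be > 0")
        _check(0.0 < self.ground_truth_threshold < 1.0,
               "ground_truth_threshold must lie in (0, 1)")


# ---------------------------------------------------------------------------
# experiment protocol
# ---------------------------------------------------------------------------

@dataclass
class ExperimentConfig:
    """One experiment: a profile, a pump, the suction module and a protocol."""

    profile: PatientProfile
    pump: PumpParams = field(default_factory=PumpParams)
    suction: SuctionParams = field(default_factory=SuctionParams)
    speed_list: list = field(default_factory=lambda: [2500.0, 2800.0, 3000.0])
    hypovolemia_step: float = 0.02          # fraction of baseline blood volume
    stop_criterion_flow_peak: float = 2.0   # [L/min]
    n_beats_per_stage: int = 15
    settle_beats_per_stage: int = 5
    max_volume_loss: float = 0.5
    solver: dict = field(default_factory=lambda: {"dt": 5.0e-4})
    noise: dict = field(default_factory=lambda: {
        "enabled": False, "q_est_sd": 0.05, "omega_sd": 2.0,
        "current_sd": 0.005, "power_sd": 0.01})
    seed: int = 0
    #: per-profile (suction, non-suction) beat quotas used by the full protocol
    beat_quotas: dict = field(default_factory=lambda: {
        "DCM": [183, 19], "RCM": [168, 21]})

    def __post_init__(self) -> None:
        self.speed_list = [float(s) for s in self.speed_list]
        self.validate()

    def validate(self) -> None:
        _check(self.stop_criterion_flow_peak > 0,
               "stop_criterion_flow_peak must be > 0")
        _check(0 < self.hypovolemia_step < 0.2,
               f"hypovolemia_step must be a small fraction, "
               f"got {self.hypovolemia_step}")
        _check(self.n_beats_per_stage >= 1, "n_beats_per_stage must be >= 1")
        for s in self.speed_list:
            _check(1800.0 <= s <= 4000.0,
                   f"protocol speed {s} rpm outside supported range")
        _check(self.solver.get("dt", 5e-4) <= 1.0e-3,
               "solver dt must be <= 1 ms")


# ---------------------------------------------------------------------------
# (de)serialization
# ---------------------------------------------------------------------------

def _profile_from_dict(d: dict) -> PatientProfile:
    d = copy.deepcopy(d)
    kwargs = {}
    for f in dataclasses.fields(PatientProfile):
        if f.default is dataclasses.MISSING and \
                f.default_factory is dataclasses.MISSING:  # type: ignore[misc]
            kwargs[f.name] = _require(d, f.name, "profile")
        elif f.name in d:
            kwargs[f.name] = d[f.name]
    return PatientProfile(**kwargs)


def _dataclass_from_dict(cls, d: dict):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(d) - names
    if unknown:
        raise ConfigurationError(
            f"unknown field(s) {sorted(unknown)} in {cls.__name__} section")
    return cls(**d)


def config_from_dict(d: dict) -> ExperimentConfig:
    """Build a validated :class:`ExperimentConfig` from plain mappings."""
    prof_raw = _require(d, "profile", "experiment config")
    if isinstance(prof_raw, str):
        profile = builtin_profile(prof_raw)
    else:
        profile = _profile_from_dict(prof_raw)
    kwargs: dict[str, Any] = {"profile": profile}
    if "pump" in d:
        kwargs["pump"] = _dataclass_from_dict(PumpParams, d["pump"])
    if "suction" in d:
        kwargs["suction"] = _dataclass_from_dict(SuctionParams, d["suction"])
    for f in dataclasses.fields(ExperimentConfig):
        if f.name in ("profile", "pump", "suction"):
            continue
        if f.name in d:
            kwargs[f.name] = d[f.name]
    return ExperimentConfig(**kwargs)


def config_to_dict(config: ExperimentConfig) -> dict:
    d = dataclasses.asdict(config)
    d["pump"]["hq_coeffs"] = list(d["pump"]["hq_coeffs"])
    return d


def load_config(path: str | Path) -> ExperimentConfig:
    """Load and validate an experiment configuration from YAML or JSON."""
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"config file not found: {path}")
    with open(path) as fh:
        try:
            raw = yaml.safe_load(fh)
        except yaml.YAMLError as exc:
            raise ConfigurationError(f"cannot parse {path}: {exc}") from exc
    if not isinstance(raw, dict):
        raise ConfigurationError(f"{path} does not contain a mapping")
    return config_from_dict(raw)


def save_config(config: ExperimentConfig, path: str | Path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(config), fh, sort_keys=False)


def builtin_profile(name: str) -> PatientProfile:
    """Return one of the calibrated built-in heart-failure profiles.

    ``"DCM"`` is a severe dilated cardiomyopathy (large, weakly contracting
    LV, Ees 0.4 mmHg/mL); ``"RCM"`` a restrictive cardiomyopathy (small stiff
    LV, Ees 3.3 mmHg/mL).  Both are supported by the pump at 2,800 rpm in
    their baseline state.
    """
    from ._profiles import BUILTIN_PROFILES

    key = name.upper()
    if key not in BUILTIN_PROFILES:
        raise LookupError(
            f"unknown profile '{name}'; valid names: "
            f"{sorted(BUILTIN_PROFILES)}")
    return _profile_from_dict(BUILTIN_PROFILES[key])


def default_config(profile: str | PatientProfile = "DCM",
                   **overrides) -> ExperimentConfig:
    """Convenience constructor with calibrated pump/suction defaults."""
    if isinstance(profile, str):
        profile = builtin_profile(profile)
    return ExperimentConfig(profile=profile, **overrides)
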