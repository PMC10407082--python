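"""Coupled simulation engine and experiment protocols.

Couples the closed-loop circulation, the rotary pump and the collapsible-apex
suction module into one ODE system integrated with a fixed-step RK4 scheme
(default dt = 0.5 ms, recorded on an exact 1-kHz grid).  Pump telemetry
(speed, current, power, estimated flow) is generated at the internal rate and
decimated to 50 Hz with an anti-alias FIR filter, mirroring how device data
loggers sample the two signal families at different rates.

State vector (12):
  0..7   compartment volumes [mL] (LV, LA, RV, RA, SA, SV, PA, PV)
  8      pump flow q [mL/s] (cannula inertance)
  9      impeller speed ω [rad/s]
  10     speed-controller integral [rad/s s]
  11     apex collapse fraction [0, 1]
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field

import numpy as np

from .cardio import CirculationModel
from .config import ExperimentConfig, PatientProfile, builtin_profile
from .pump import RPM_TO_RAD, MLPS_TO_LPM, head_pressure
from .suction import collapse_rate, inflow_resistance, update_latch

HEMO_RATE = 1000.0   # [Hz]
PUMP_RATE = 50.0     # [Hz]
DECIMATION = int(HEMO_RATE / PUMP_RATE)


def _slew_limit(x: np.ndarray, down_per_sample: float,
                up_per_sample: float) -> np.ndarray:
    """Rate-limit a signal: output follows input within the per-sample caps."""
    y = np.empty_like(x)
    acc = x[0]
    for i in range(len(x)):
        step = x[i] - acc
        if step > up_per_sample:
            step = up_per_sample
        elif step < -down_per_sample:
            step = -down_per_sample
        acc += step
        y[i] = acc
    return y


class ConvergenceError(RuntimeError):
    """No periodic steady state within the allotted number of beats."""


class ProtocolError(RuntimeError):
    """A protocol stop criterion could not be reached."""


# ---------------------------------------------------------------------------
# records and summaries
# ---------------------------------------------------------------------------

@dataclass
class SignalRecord:
    """Multichannel recording: hemodynamics at 1 kHz, pump channels at 50 Hz."""

    t: np.ndarray          # hemo time base [s]
    p_lv: np.ndarray
    p_ao: np.ndarray
    p_apex: np.ndarray
    p_la: np.ndarray
    p_pa: np.ndarray
    v_lv: np.ndarray
    v_total: np.ndarray
    collapse: np.ndarray
    q_pump: np.ndarray     # true pump flow [mL/s]
    q_total: np.ndarray    # aortic-valve + pump flow [mL/s]
    t_pump: np.ndarray     # pump time base [s]
    omega: np.ndarray      # [rpm]
    i_motor: np.ndarray    # [A]
    power: np.ndarray      # [W]
    q_est: np.ndarray      # estimated flow [L/min]
    meta: dict = field(default_factory=dict)

    def hemo_frame(self):
        import pandas as pd
        return pd.DataFrame({
            "time_s": self.t, "p_lv_mmHg": self.p_lv, "p_ao_mmHg": self.p_ao,
            "p_apex_mmHg": self.p_apex, "p_la_mmHg": self.p_la,
            "p_pa_mmHg": self.p_pa, "v_lv_mL": self.v_lv,
            "v_total_mL": self.v_total, "collapse_fraction": self.collapse,
            "q_pump_mL_s": self.q_pump, "q_total_mL_s": self.q_total,
        })

    def pump_frame(self):
        import pandas as pd
        return pd.DataFrame({
            "time_s": self.t_pump, "speed_rpm": self.omega,
            "current_A": self.i_motor, "power_W": self.power,
            "flow_est_lpm": self.q_est,
        })


@dataclass
class HemodynamicSummary:
    """Beat-averaged hemodynamics over whole beats of a recording."""

    co: float                   # total systemic flow [L/min]
    sap_sys: float
    sap_dia: float
    sap_mean: float
    pap_sys: float
    pap_dia: float
    pap_mean: float
    pcwp: float                 # beat-mean left atrial pressure [mmHg]
    edv: float
    esv: float
    pump_flow_mean: float       # [L/min]
    pump_flow_peak: float       # 50-Hz estimated-flow peak [L/min]
    n_beats: int

    def __post_init__(self) -> None:
        if not (self.sap_sys >= self.sap_mean >= self.sap_dia):
            raise ValueError("arterial pressures must satisfy sys >= mean >= dia")
        if self.edv < self.esv:
            raise ValueError("edv must be >= esv")

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in (
            "co", "sap_sys", "sap_dia", "sap_mean", "pap_sys", "pap_dia",
            "pap_mean", "pcwp", "edv", "esv", "pump_flow_mean",
            "pump_flow_peak", "n_beats")}


def summarize(record: SignalRecord, hr: float) -> HemodynamicSummary:
    """Compute the beat-averaged summary over the whole beats of a record."""
    period = 60.0 / hr
    dt = 1.0 / HEMO_RATE
    samples_per_beat = period / dt
    n_beats = int(math.floor(len(record.t) / samples_per_beat))
    if n_beats < 1:
        raise ValueError("record shorter than one beat")

    def per_beat(x, fn):
        vals = []
        for b in range(n_beats):
            i0 = int(round(b * samples_per_beat))
            i1 = int(round((b + 1) * samples_per_beat))
            vals.append(fn(x[i0:i1]))
        return float(np.mean(vals))

    n_used = int(round(n_beats * samples_per_beat))
    co = float(np.mean(record.q_total[:n_used])) * MLPS_TO_LPM
    return HemodynamicSummary(
        co=co,
        sap_sys=per_beat(record.p_ao, np.max),
        sap_dia=per_beat(record.p_ao, np.min),
        sap_mean=float(np.mean(record.p_ao[:n_used])),
        pap_sys=per_beat(record.p_pa, np.max),
        pap_dia=per_beat(record.p_pa, np.min),
        pap_mean=float(np.mean(record.p_pa[:n_used])),
        pcwp=float(np.mean(record.p_la[:n_used])),
        edv=per_beat(record.v_lv, np.max),
        esv=per_beat(record.v_lv, np.min),
        pump_flow_mean=float(np.mean(record.q_pump[:n_used])) * MLPS_TO_LPM,
        pump_flow_peak=float(np.max(record.q_est)),
        n_beats=n_beats,
    )


# ---------------------------------------------------------------------------
# simulator
# ---------------------------------------------------------------------------

class Simulator:
    """Integrates the coupled circulation/pump/suction system."""

    N_STATES = 12

    def __init__(self, config: ExperimentConfig):
        self.config = config
        self.circ = CirculationModel(config.profile)
        self.pump = config.pump
        self.suction = config.suction
        self.dt = float(config.solver.get("dt", 5.0e-4))
        self.record_stride = max(1, int(round((1.0 / HEMO_RATE) / self.dt)))
        self.rng = np.random.default_rng(config.seed)
        self.pressure_floor_hits = 0
        self.t = 0.0
        self.latched = False
        self.y = self._initial_state()

    # -- setup ---------------------------------------------------------------

    def _initial_state(self) -> np.ndarray:
        y = np.zeros(self.N_STATES)
        y[:8] = self.circ.initial_volumes()
        q0 = (self.config.profile.target_hemodynamics.get("co", 4.5)
              / MLPS_TO_LPM)
        y[8] = q0
        omega0 = self.pump.speed_setpoint * RPM_TO_RAD
        y[9] = omega0
        # start the integral near torque equilibrium to shorten settling
        t_load = (self.pump.flow_torque_coeff * q0 * omega0
                  + self.pump.friction_coeff * omega0)
        y[10] = t_load / (self.pump.torque_constant
                          * self.pump.controller_gains["ki"])
        y[11] = 0.0
        return y

    def set_speed(self, rpm: float) -> None:
        self.pump.speed_setpoint = float(rpm)

    def withdraw_volume(self, dv_ml: float) -> None:
        """Remove blood volume from the stressed venous compartments.

        Mimics hypovolemia: the withdrawal is split between systemic and
        pulmonary venous compartments in proportion to their stressed volume.
        """
        y = self.y
        s_sv = max(y[5] - self.circ.v0_sv, 1.0)
        s_pv = max(y[7] - self.circ.v0_pv, 1.0)
        total = s_sv + s_pv
        y[5] -= dv_ml * s_sv / total
        y[7] -= dv_ml * s_pv / total

    # -- dynamics -------------------------------------------------------------

    def _rhs(self, t: float, y: np.ndarray):
        """Full-system derivative; also returns the auxiliary observables."""
        q = y[8]
        omega = y[9]           # rad/s
        xint = y[10]
        c = min(max(y[11], 0.0), 1.0)

        dv, p, flows = self.circ.derivatives(
            y[:8], t, q_lv_out=q, q_ao_in=q)
        p_lv, p_sa = p[0], p[4]

        # suction module
        r_in = inflow_resistance(c, self.suction)
        p_apex = p_lv - r_in * q
        dc = collapse_rate(p_lv, c, self.suction, self.latched)

        # pump hydraulics (cannula inertance)
        omega_rpm = omega / RPM_TO_RAD
        dp_head = head_pressure(q * MLPS_TO_LPM, omega_rpm,
                                self.pump.hq_coeffs)
        dq = (p_lv - r_in * q + dp_head
              - self.pump.graft_resistance * q - p_sa) \
            / self.pump.cannula_inertance

        # PI speed controller with anti-windup (continuous form)
        gains = self.pump.controller_gains
        err = self.pump.speed_setpoint * RPM_TO_RAD - omega
        i_raw = gains["kp"] * err + gains["ki"] * xint
        i_max = gains.get("i_max", 3.0)
        if i_raw > i_max:
            i_cmd, dxint = i_max, (0.0 if err > 0.0 else err)
        elif i_raw < 0.0:
            i_cmd, dxint = 0.0, (0.0 if err < 0.0 else err)
        else:
            i_cmd, dxint = i_raw, err

        # impeller/motor dynamics
        t_hyd = self.pump.flow_torque_coeff * q * omega
        t_fric = self.pump.friction_coeff * omega
        domega = (self.pump.torque_constant * i_cmd - t_hyd - t_fric) \
            / self.pump.impeller_inertia

        dy = np.empty(self.N_STATES)
        dy[:8] = dv
        dy[8] = dq
        dy[9] = domega
        dy[10] = dxint
        dy[11] = dc
        aux = (p_lv, p_sa, p_apex, p[1], p[6], flows["q_av"],
               i_cmd, self.pump.torque_constant * i_cmd * omega)
        return dy, aux

    def advance(self, duration: float, record: bool = False):
        """Integrate for ``duration`` seconds; optionally record channels."""
        n_steps = int(round(duration / self.dt))
        dt = self.dt
        y = self.y
        t = self.t
        if record:
            n_rec = n_steps // self.record_stride
            rec = np.empty((n_rec, 14))
        i_rec = 0
        for step in range(n_steps):
            k1, aux = self._rhs(t, y)
            # hysteretic squeeze actuation, updated once per step on the
            # current chamber pressure
            self.latched = update_latch(aux[0], self.latched, self.suction)
            if record and step % self.record_stride == 0 \
                    and i_rec < (n_steps // self.record_stride):
                p_lv, p_sa, p_apex, p_la, p_pa, q_av, i_cmd, power = aux
                rec[i_rec] = (t, p_lv, p_sa, p_apex, p_la, p_pa,
                              y[0], y[:8].sum(), y[11], y[8],
                              q_av + y[8], y[9] / RPM_TO_RAD, i_cmd, power)
                i_rec += 1
            k2, _ = self._rhs(t + 0.5 * dt, y + 0.5 * dt * k1)
            k3, _ = self._rhs(t + 0.5 * dt, y + 0.5 * dt * k2)
            k4, _ = self._rhs(t + dt, y + dt * k3)
            y = y + (dt / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
            y[11] = min(max(y[11], 0.0), 1.0)
            t += dt
        self.y = y
        self.t = t
        if record:
            return self._make_record(rec[:i_rec])
        return None

    # -- recording ------------------------------------------------------------

    def _make_record(self, rec: np.ndarray) -> SignalRecord:
        t = rec[:, 0]
        omega_1k = rec[:, 11]
        i_1k = rec[:, 12]
        power_1k = rec[:, 13]

        # on-device flow estimate at the internal rate, then telemetry
        # smoothing (device-like averaging) and 50-Hz decimation
        omega_rad = omega_1k * RPM_TO_RAD
        est = self.pump.estimator_coeffs
        q_est_1k = (est["torque_constant"] * i_1k
                    - est["friction_coeff"] * omega_rad) \
            / (est["flow_torque_coeff"] * omega_rad) * MLPS_TO_LPM
        # device-style reporting filter: a causal low-pass (the device lags
        # reality) followed by a slew-rate limit, mirroring how controllers
        # smooth and rate-limit the displayed flow estimate
        from scipy.signal import butter, lfilter, lfilter_zi
        b, a = butter(4, self.pump.est_filter_cutoff_hz,
                      fs=HEMO_RATE, btype="low")
        zi = lfilter_zi(b, a) * q_est_1k[0]
        q_est_1k, _ = lfilter(b, a, q_est_1k, zi=zi)
        q_est_1k = _slew_limit(q_est_1k,
                               self.pump.est_slew_down / HEMO_RATE,
                               self.pump.est_slew_up / HEMO_RATE)

        def dec(x):
            # block-average decimation: a 20-sample boxcar anti-alias filter
            # with no edge ringing (the channels carry no content near the
            # 25-Hz Nyquist limit of the pump telemetry)
            n = (len(x) // DECIMATION) * DECIMATION
            return x[:n].reshape(-1, DECIMATION).mean(axis=1)

        t_pump = t[: (len(t) // DECIMATION) * DECIMATION: DECIMATION]
        omega50, i50, power50, q_est50 = (dec(omega_1k), dec(i_1k),
                                          dec(power_1k), dec(q_est_1k))
        noise = self.config.noise
        if noise.get("enabled", False):
            omega50 = omega50 + self.rng.normal(
                0.0, noise.get("omega_sd", 2.0), omega50.shape)
            i50 = i50 + self.rng.normal(
                0.0, noise.get("current_sd", 0.005), i50.shape)
            power50 = power50 + self.rng.normal(
                0.0, noise.get("power_sd", 0.01), power50.shape)
            q_est50 = q_est50 + self.rng.normal(
                0.0, noise.get("q_est_sd", 0.05), q_est50.shape)

        return SignalRecord(
            t=t, p_lv=rec[:, 1], p_ao=rec[:, 2], p_apex=rec[:, 3],
            p_la=rec[:, 4], p_pa=rec[:, 5], v_lv=rec[:, 6],
            v_total=rec[:, 7], collapse=rec[:, 8], q_pump=rec[:, 9],
            q_total=rec[:, 10], t_pump=t_pump, omega=omega50, i_motor=i50,
            power=power50, q_est=q_est50,
            meta={"profile": self.config.profile.name,
                  "speed_rpm": self.pump.speed_setpoint,
                  "hr": self.circ.hr},
        )

    # -- steady state ----------------------------------------------------------

    def settle(self, max_beats: int = 200, tol: float = 0.005,
               window: int = 3) -> int:
        """Integrate beat by beat until CO and EDV are periodic.

        The criterion is a relative change of both beat CO and EDV below
        ``tol`` over ``window`` consecutive beats.
        """
        period = self.circ.period
        history: list[tuple[float, float]] = []
        for beat in range(max_beats):
            rec = self.advance(period, record=True)
            co = float(np.mean(rec.q_total))
            edv = float(np.max(rec.v_lv))
            history.append((co, edv))
            if len(history) > window:
                ref_co, ref_edv = history[-1]
                ok = all(
                    abs(c - ref_co) / max(abs(ref_co), 1e-9) < tol
                    and abs(e - ref_edv) / max(ref_edv, 1e-9) < tol
                    for c, e in history[-window - 1:-1])
                if ok:
                    return beat + 1
        raise ConvergenceError(
            f"no periodic steady state within {max_beats} beats; "
            f"last beats (CO mL/s, EDV mL): {history[-5:]}")


# ---------------------------------------------------------------------------
# protocols
# ---------------------------------------------------------------------------

def run_steady(config: ExperimentConfig, duration: float = 20.0
               ) -> tuple[SignalRecord, HemodynamicSummary]:
    """Settle the configured system, then record ``duration`` seconds."""
    sim = Simulator(copy.deepcopy(config))
    sim.settle()
    record = sim.advance(duration, record=True)
    record.meta["stage"] = 0
    record.meta["volume_fraction"] = 1.0
    return record, summarize(record, config.profile.hr)


def hypovolemia_ramp(config: ExperimentConfig, speed: float
                     ) -> list[SignalRecord]:
    """Stepwise blood-volume reduction until suction plus low-flow criterion.

    Stage 0 is the baseline; each further stage removes
    ``config.hypovolemia_step`` of the baseline blood volume from the venous
    compartments.  The ramp ends at the first stage with at least one
    ground-truth suction beat AND a 50-Hz estimated-flow peak below
    ``config.stop_criterion_flow_peak``.
    """
    if speed not in config.speed_list:
        raise ProtocolError(
            f"speed {speed} rpm is not in the configured speed list "
            f"{config.speed_list}")
    config = copy.deepcopy(config)
    config.pump.speed_setpoint = float(speed)
    sim = Simulator(config)
    sim.settle()
    period = sim.circ.period
    tbv0 = config.profile.total_blood_volume
    gt_thr = config.suction.ground_truth_threshold

    records: list[SignalRecord] = []
    removed = 0.0
    stage = 0
    while True:
        rec = sim.advance(config.n_beats_per_stage * period, record=True)
        rec.meta.update({
            "stage": stage,
            "volume_fraction": (tbv0 - removed) / tbv0,
        })
        records.append(rec)
        suction_seen = bool(np.any(rec.collapse > gt_thr))
        low_flow = float(np.max(rec.q_est)) < config.stop_criterion_flow_peak
        if suction_seen and low_flow:
            return records
        if removed >= config.max_volume_loss * tbv0:
            raise ProtocolError(
                f"stop criterion not reached after losing "
                f"{removed / tbv0:.0%} of blood volume at {speed} rpm")
        dv = config.hypovolemia_step * tbv0
        sim.withdraw_volume(dv)
        removed += dv
        sim.advance(config.settle_beats_per_stage * period)
        stage += 1


# ---------------------------------------------------------------------------
# beat dataset (full protocol)
# ---------------------------------------------------------------------------

@dataclass
class BeatSample:
    """One segmented beat: 50-Hz pump channels plus the ground-truth flag."""

    profile: str
    speed: float
    stage: int
    beat_index: int
    t0: float
    fs: float
    q_est: np.ndarray
    omega: np.ndarray
    gt_suction: bool
    diastole_offset: int = 0    # diastole start relative to the beat window


@dataclass
class BeatDataset:
    """Labeled beats pooled over profiles, speeds and volume stages."""

    beats: list

    def __len__(self) -> int:
        return len(self.beats)

    def counts(self) -> dict:
        out: dict = {}
        for b in self.beats:
            key = b.profile
            s, n = out.get(key, (0, 0))
            out[key] = (s + int(b.gt_suction), n + int(not b.gt_suction))
        return out

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame([{
            "profile": b.profile, "speed_rpm": b.speed, "stage": b.stage,
            "beat_index": b.beat_index, "t0_s": b.t0, "fs_hz": b.fs,
            "n_samples": len(b.q_est), "gt_suction": b.gt_suction,
            "diastole_offset": b.diastole_offset,
        } for b in self.beats])

    def save(self, directory) -> None:
        import pandas as pd
        from pathlib import Path
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.to_frame().to_csv(directory / "beats.csv", index=False)
        rows = []
        for i, b in enumerate(self.beats):
            for j in range(len(b.q_est)):
                rows.append((i, j, b.q_est[j], b.omega[j]))
        pd.DataFrame(rows, columns=[
            "beat_id", "sample", "flow_est_lpm", "speed_rpm"]).to_csv(
            directory / "beat_signals.csv", index=False)

    @classmethod
    def load(cls, directory) -> "BeatDataset":
        import pandas as pd
        from pathlib import Path
        directory = Path(directory)
        meta = pd.read_csv(directory / "beats.csv")
        sig = pd.read_csv(directory / "beat_signals.csv")
        groups = dict(tuple(sig.groupby("beat_id")))
        beats = []
        for i, row in meta.iterrows():
            g = groups[i].sort_values("sample")
            beats.append(BeatSample(
                profile=row["profile"], speed=row["speed_rpm"],
                stage=int(row["stage"]), beat_index=int(row["beat_index"]),
                t0=row["t0_s"], fs=row["fs_hz"],
                q_est=g["flow_est_lpm"].to_numpy(),
                omega=g["speed_rpm"].to_numpy(),
                gt_suction=bool(row["gt_suction"]),
                diastole_offset=int(row.get("diastole_offset", 0))))
        return cls(beats=beats)


def _beats_from_record(record: SignalRecord, gt_threshold: float
                       ) -> list[BeatSample]:
    """Segment one stage record into labeled beats."""
    from .detection import detect_beats

    beats = detect_beats(record.q_est, fs=PUMP_RATE)
    out = []
    for k, beat in enumerate(beats):
        h0 = beat.start_index * DECIMATION
        h1 = beat.end_index * DECIMATION
        window = record.collapse[h0:h1]
        gt = bool(np.any(window > gt_threshold)) if window.size else False
        out.append(BeatSample(
            profile=record.meta.get("profile", "?"),
            speed=record.meta.get("speed_rpm", float("nan")),
            stage=record.meta.get("stage", -1),
            beat_index=k,
            t0=float(record.t_pump[beat.start_index]),
            fs=PUMP_RATE,
            q_est=record.q_est[beat.start_index:beat.end_index].copy(),
            omega=record.omega[beat.start_index:beat.end_index].copy(),
            gt_suction=gt,
            diastole_offset=beat.diastole_start_index - beat.start_index))
    return out


def _apply_quota(beats_by_speed: dict, quota: int) -> list[BeatSample]:
    """Round-robin selection across speeds, preserving within-speed order."""
    selected: list[BeatSample] = []
    queues = [list(v) for v in beats_by_speed.values()]
    while len(selected) < quota and any(queues):
        for q in queues:
            if q and len(selected) < quota:
                selected.append(q.pop(0))
    return selected


def full_protocol(config: ExperimentConfig,
                  profiles: list[PatientProfile] | None = None
                  ) -> BeatDataset:
    """Run both profiles over the speed grid with hypovolemia ramps.

    Pools the segmented, ground-truth-labeled beats and trims them to the
    configured per-profile quotas (suction / non-suction counts), selecting
    round-robin across pump speeds in ramp order so every speed contributes.
    """
    if profiles is None:
        profiles = [builtin_profile("DCM"), builtin_profile("RCM")]
    all_beats: list[BeatSample] = []
    for profile in profiles:
        cfg = copy.deepcopy(config)
        cfg.profile = profile
        suction_by_speed: dict = {}
        nonsuction_by_speed: dict = {}
        for speed in cfg.speed_list:
            records = hypovolemia_ramp(cfg, speed)
            s_list: list[BeatSample] = []
            n_list: list[BeatSample] = []
            for rec in records:
                for b in _beats_from_record(
                        rec, cfg.suction.ground_truth_threshold):
                    (s_list if b.gt_suction else n_list).append(b)
            suction_by_speed[speed] = s_list
            nonsuction_by_speed[speed] = n_list
        quota_s, quota_n = config.beat_quotas.get(
            profile.name, [10 ** 9, 10 ** 9])
        all_beats.extend(_apply_quota(suction_by_speed, quota_s))
        all_beats.extend(_apply_quota(nonsuction_by_speed, quota_n))
    return BeatDataset(beats=all_beats)
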