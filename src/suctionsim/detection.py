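"""Beat-level suction detection from 50-Hz pump telemetry.

Pipeline: (1) segment cardiac cycles from the estimated pump-flow signal —
beat onset is the beginning of diastole, located as the flow minimum that
follows the systolic decay; (2) extract three suction features per beat:

* ``d_omega_min`` — minimum impeller speed pulsatility [rpm]: the minimum
  over the beat of speed minus the beat-median speed (negative);
* ``dqdt_min`` — minimum (most negative) two-point slope of the estimated
  flow [L/min/s];
* ``t_dqdt_max`` — timing of the maximum positive flow slope, normalized to
  the cycle from the beginning of diastole, wrapped into [0, 1];

(3) classify each beat with a fixed-order, 3-split binary decision tree
against calibrated thresholds.  A beat is called suction as soon as one split
fires; ties (exact threshold equality) classify as suction — the conservative
choice for a safety-relevant detector.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

import yaml


class FeatureError(ValueError):
    """Beat too short (or otherwise unusable) for feature extraction."""


class ClassificationError(ValueError):
    """Non-finite feature handed to the classifier."""


class CalibrationError(ValueError):
    """Threshold calibration impossible (e.g. single-class input)."""


# ---------------------------------------------------------------------------
# types
# ---------------------------------------------------------------------------

@dataclass
class Beat:
    """One segmented cardiac cycle, half-open [start_index, end_index)."""

    start_index: int
    end_index: int
    fs: float = 50.0
    diastole_start_index: int | None = None

    def __post_init__(self) -> None:
        if self.end_index <= self.start_index:
            raise ValueError("beat end must exceed start")
        if self.diastole_start_index is None:
            self.diastole_start_index = self.start_index

    @property
    def duration(self) -> float:
        return (self.end_index - self.start_index) / self.fs


@dataclass
class SuctionFeatureSet:
    """The three per-beat classifier features."""

    d_omega_min: float     # [rpm], negative
    dqdt_min: float        # [L/min/s]
    t_dqdt_max: float      # normalized cycle fraction in [0, 1]

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.dqdt_min, self.d_omega_min, self.t_dqdt_max)


@dataclass
class TreeThresholds:
    """Thresholds of the 3-split tree, compared in fixed order.

    Split order: dqdt_min first, then d_omega_min, then t_dqdt_max.  The
    shipped defaults are calibrated constants (grid search on the full
    simulated protocol dataset); they are overridable from YAML.
    """

    thr_dqdt_min: float = -0.925    # [L/min/s]
    thr_d_omega_min: float = -35.0  # [rpm]
    thr_t_dqdt_max: float = 0.93    # normalized

    def __post_init__(self) -> None:
        for name in ("thr_dqdt_min", "thr_d_omega_min", "thr_t_dqdt_max"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump({
                "thr_dqdt_min": float(self.thr_dqdt_min),
                "thr_d_omega_min": float(self.thr_d_omega_min),
                "thr_t_dqdt_max": float(self.thr_t_dqdt_max)}, fh)

    @classmethod
    def load(cls, path) -> "TreeThresholds":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


#: calibrated default thresholds (see TreeThresholds docstring)
DEFAULT_THRESHOLDS = TreeThresholds()


# ---------------------------------------------------------------------------
# beat detection
# ---------------------------------------------------------------------------

def detect_beats(q_est: np.ndarray, fs: float = 50.0,
                 refractory: float = 0.3, smooth_window: int = 7,
                 min_duration: float = 0.3, max_duration: float = 2.0
                 ) -> list[Beat]:
    """Segment cardiac cycles from the 50-Hz estimated pump flow.

    Beat onsets are placed at the minima of a lightly smoothed copy of the
    flow signal (the smoothing only steers onset placement; features are
    extracted from the raw channel).  The beginning of diastole is marked at
    the onset of the post-systolic decline, located at the smoothed-flow
    crest of the cycle.  Windows are contiguous, non-overlapping, half-open;
    a flat signal yields zero beats with a warning.
    """
    q_est = np.asarray(q_est, dtype=float)
    if q_est.size < int(5 * fs):
        raise ValueError("need at least 5 s of signal to segment beats")
    span = float(np.ptp(q_est))
    if span < 1.0e-3:
        warnings.warn("flat flow signal: no beats detected", stacklevel=2)
        return []

    smooth = _moving_average(q_est, smooth_window)
    distance = max(1, int(round(refractory * fs)))
    minima, _ = find_peaks(-smooth, distance=distance,
                           prominence=0.05 * span)
    beats: list[Beat] = []
    for i0, i1 in zip(minima[:-1], minima[1:]):
        dur = (i1 - i0) / fs
        if min_duration <= dur <= max_duration:
            ds = int(i0 + np.argmax(smooth[i0:i1]))
            beats.append(Beat(start_index=int(i0), end_index=int(i1), fs=fs,
                              diastole_start_index=ds))
    return beats


def _moving_average(x: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return x
    kernel = np.ones(window)
    norm = np.convolve(np.ones_like(x), kernel, mode="same")
    return np.convolve(x, kernel, mode="same") / norm


# ---------------------------------------------------------------------------
# features
# ---------------------------------------------------------------------------

def extract_features(beat: Beat, q_est: np.ndarray, omega: np.ndarray,
                     median_prefilter: bool = False) -> SuctionFeatureSet:
    """Extract the three suction features for one beat.

    Derivatives are two-point finite differences of the raw 50-Hz estimated
    flow (no smoothing by default, preserving the sharp suction transients);
    ``median_prefilter`` applies a 3-sample median filter for noisy external
    telemetry.  The speed pulsatility is referenced to the beat-median speed,
    making it robust to slow setpoint drift.
    """
    i0, i1 = beat.start_index, beat.end_index
    n = i1 - i0
    if n < 4:
        raise FeatureError(f"beat of {n} samples is too short for features")
    q = np.asarray(q_est, dtype=float)[i0:i1]
    w = np.asarray(omega, dtype=float)[i0:i1]
    if median_prefilter:
        from scipy.signal import medfilt
        q = medfilt(q, kernel_size=3)

    d = np.diff(q) * beat.fs                      # [L/min/s]
    dqdt_min = float(np.min(d))
    i_max = int(np.argmax(d))
    ds = beat.diastole_start_index - i0
    t_dqdt_max = float(((i_max - ds) % n) / n)    # wrapped into [0, 1)

    d_omega_min = float(np.min(w - np.median(w)))
    return SuctionFeatureSet(d_omega_min=d_omega_min, dqdt_min=dqdt_min,
                             t_dqdt_max=t_dqdt_max)


# ---------------------------------------------------------------------------
# classifier
# ---------------------------------------------------------------------------

def classify(features: SuctionFeatureSet,
             thresholds: TreeThresholds = DEFAULT_THRESHOLDS
             ) -> tuple[str, int]:
    """3-split decision tree: returns ('suction'|'non_suction', branch id).

    Branch ids: 1 = flow-slope split, 2 = speed-pulsatility split,
    3 = timing split, 0 = non-suction leaf.
    """
    vals = (features.dqdt_min, features.d_omega_min, features.t_dqdt_max)
    if not all(np.isfinite(v) for v in vals):
        raise ClassificationError(f"non-finite feature(s): {features}")
    if features.dqdt_min >= thresholds.thr_dqdt_min:
        return "suction", 1
    if features.d_omega_min >= thresholds.thr_d_omega_min:
        return "suction", 2
    if features.t_dqdt_max >= thresholds.thr_t_dqdt_max:
        return "suction", 3
    return "non_suction", 0


def classify_many(feature_rows: np.ndarray, thresholds: TreeThresholds
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized tree over rows (dqdt_min, d_omega_min, t_dqdt_max)."""
    f = np.asarray(feature_rows, dtype=float)
    b1 = f[:, 0] >= thresholds.thr_dqdt_min
    b2 = f[:, 1] >= thresholds.thr_d_omega_min
    b3 = f[:, 2] >= thresholds.thr_t_dqdt_max
    branch = np.zeros(len(f), dtype=int)
    branch[b3] = 3                # later assignments take split-order priority
    branch[b2] = 2
    branch[b1] = 1
    pred = b1 | b2 | b3
    return pred, branch


def calibrate_thresholds(feature_rows: np.ndarray, labels: np.ndarray,
                         n_grid: int = 40) -> TreeThresholds:
    """Grid-search thresholds maximizing balanced accuracy.

    Respects the fixed split order (the order only affects branch attribution,
    not the OR-decision).  Candidate thresholds are quantiles of the pooled
    feature values.  Ties in balanced accuracy resolve toward the higher
    specificity, then toward the most permissive (most negative) flow-slope
    threshold so the first split carries as many suction calls as possible,
    matching the fixed split-order design.
    """
    f = np.asarray(feature_rows, dtype=float)
    y = np.asarray(labels, dtype=bool)
    if y.sum() < 20 or (~y).sum() < 20:
        raise CalibrationError(
            f"need >= 20 beats per class, got {int(y.sum())} suction / "
            f"{int((~y).sum())} non-suction")

    qs = np.linspace(0.0, 1.0, n_grid)
    grids = [np.unique(np.quantile(f[:, j], qs)) for j in range(3)]
    # candidate = midpoints between consecutive pooled values plus extremes
    grids = [np.concatenate((
        [g[0] - 1.0], (g[:-1] + g[1:]) / 2.0, [g[-1] + 1.0])) for g in grids]

    n_pos = y.sum()
    n_neg = (~y).sum()
    best = None
    for t1 in grids[0]:
        c1 = f[:, 0] >= t1
        for t2 in grids[1]:
            c12 = c1 | (f[:, 1] >= t2)
            for t3 in grids[2]:
                pred = c12 | (f[:, 2] >= t3)
                tp = np.count_nonzero(pred & y)
                tn = np.count_nonzero(~pred & ~y)
                bal = 0.5 * (tp / n_pos + tn / n_neg)
                key = (bal, tn / n_neg, -t1)
                if best is None or key > best[0]:
                    best = (key, TreeThresholds(
                        thr_dqdt_min=float(t1), thr_d_omega_min=float(t2),
                        thr_t_dqdt_max=float(t3)))
    return best[1]


# ---------------------------------------------------------------------------
# telemetry I/O
# ---------------------------------------------------------------------------

TELEMETRY_COLUMNS = ("time_s", "speed_rpm", "current_A", "power_W",
                     "flow_est_lpm")


def read_telemetry(path) -> dict:
    """Read 50-Hz pump telemetry from delimited text (CSV)."""
    import pandas as pd
    df = pd.read_csv(path)
    missing = [c for c in ("time_s", "speed_rpm", "flow_est_lpm")
               if c not in df.columns]
    if missing:
        raise ValueError(f"telemetry file {path} lacks columns {missing}")
    return {c: df[c].to_numpy() for c in df.columns}


def write_telemetry(path, t, speed_rpm, current_a, power_w, flow_est_lpm
                    ) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(TELEMETRY_COLUMNS)
        for row in zip(t, speed_rpm, current_a, power_w, flow_est_lpm):
            w.writerow([f"{v:.6g}" for v in row])
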