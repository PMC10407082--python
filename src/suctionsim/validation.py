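"""Quantitative validation of the suction test bench.

Runs the detection pipeline over a labeled beat dataset and assembles the
confusion statistics against the simulator's ground truth (sensitivity =
TP/(TP+FN) with suction as the positive class, specificity = TN/(TN+FP)),
per-feature boxplot summaries for each class, and distribution comparisons
(Shapiro-Wilk normality check, then a two-tailed t-test if both samples are
normal, otherwise a Mann-Whitney U test).
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import stats

from .detection import (DEFAULT_THRESHOLDS, Beat, SuctionFeatureSet,
                        TreeThresholds, classify, extract_features)
from .engine import BeatDataset


class UndefinedMetricError(ValueError):
    """A confusion metric is undefined because one class is absent."""


# ---------------------------------------------------------------------------
# confusion statistics
# ---------------------------------------------------------------------------

@dataclass
class ConfusionStats:
    tp: int
    fn: int
    tn: int
    fp: int
    sensitivity: float
    specificity: float


def confusion_stats(predicted, truth) -> ConfusionStats:
    """Confusion counts and rates; suction is the positive class.

    ``predicted`` and ``truth`` are boolean vectors (True = suction).
    """
    pred = np.asarray(predicted, dtype=bool)
    y = np.asarray(truth, dtype=bool)
    if pred.shape != y.shape:
        raise ValueError("label vectors must have equal length")
    if y.size == 0:
        raise UndefinedMetricError("empty label vectors")
    tp = int(np.count_nonzero(pred & y))
    fn = int(np.count_nonzero(~pred & y))
    tn = int(np.count_nonzero(~pred & ~y))
    fp = int(np.count_nonzero(pred & ~y))
    if tp + fn == 0:
        raise UndefinedMetricError(
            "sensitivity undefined: no ground-truth suction beats")
    if tn + fp == 0:
        raise UndefinedMetricError(
            "specificity undefined: no ground-truth non-suction beats")
    return ConfusionStats(tp=tp, fn=fn, tn=tn, fp=fp,
                          sensitivity=tp / (tp + fn),
                          specificity=tn / (tn + fp))


# ---------------------------------------------------------------------------
# descriptive statistics
# ---------------------------------------------------------------------------

def boxplot_stats(values) -> dict:
    """Median, quartiles (linear interpolation) and extremes of a sample."""
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("boxplot_stats needs a non-empty sample")
    return {
        "median": float(np.median(x)),
        "q1": float(np.quantile(x, 0.25)),
        "q3": float(np.quantile(x, 0.75)),
        "min": float(np.min(x)),
        "max": float(np.max(x)),
        "n": int(x.size),
    }


def compare_distributions(sample_a, sample_b, alpha: float = 0.05) -> dict:
    """Shapiro-Wilk gate, then two-tailed t-test or Mann-Whitney U.

    Returns the test used, its statistic and p-value, plus the normality
    p-values.  Zero-variance samples (Shapiro-Wilk undefined) fall back to
    Mann-Whitney with a warning.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise ValueError("compare_distributions needs n >= 3 per sample")

    def _shapiro_p(x):
        if np.ptp(x) == 0.0:
            return None
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return float(stats.shapiro(x).pvalue)

    p_a, p_b = _shapiro_p(a), _shapiro_p(b)
    degenerate = p_a is None or p_b is None
    if degenerate:
        warnings.warn("zero-variance sample: falling back to Mann-Whitney U",
                      stacklevel=2)
    if not degenerate and p_a > alpha and p_b > alpha:
        res = stats.ttest_ind(a, b)
        name = "t-test"
    else:
        res = stats.mannwhitneyu(a, b, alternative="two-sided")
        name = "mann-whitney"
    return {"test": name, "statistic": float(res.statistic),
            "p": float(res.pvalue), "shapiro_p_a": p_a, "shapiro_p_b": p_b}


# ---------------------------------------------------------------------------
# report
# ---------------------------------------------------------------------------

FEATURE_NAMES = ("dqdt_min", "d_omega_min", "t_dqdt_max")


@dataclass
class ValidationReport:
    """Machine-readable summary of one validation run."""

    confusion: dict
    sensitivity: float
    specificity: float
    branch1_fraction: float          # of detected suction beats exiting split 1
    branch_counts: dict
    feature_stats: dict              # feature -> class -> boxplot stats
    comparisons: dict                # feature -> suction vs non-suction test
    thresholds: dict
    counts: dict = field(default_factory=dict)

    def to_json(self, path=None) -> str:
        payload = dataclasses.asdict(self)
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_json(cls, path) -> "ValidationReport":
        payload = json.loads(Path(path).read_text())
        return cls(**payload)


def dataset_features(dataset: BeatDataset) -> tuple[np.ndarray, np.ndarray]:
    """Per-beat feature rows (dqdt_min, d_omega_min, t_dqdt_max) and labels."""
    rows, labels = [], []
    for b in dataset.beats:
        beat = Beat(start_index=0, end_index=len(b.q_est), fs=b.fs,
                    diastole_start_index=getattr(b, "diastole_offset", 0))
        feats = extract_features(beat, b.q_est, b.omega)
        rows.append(feats.as_tuple())
        labels.append(b.gt_suction)
    return np.asarray(rows, dtype=float), np.asarray(labels, dtype=bool)


def generate_report(dataset: BeatDataset,
                    thresholds: TreeThresholds = DEFAULT_THRESHOLDS
                    ) -> ValidationReport:
    """Detect → extract → classify over all beats and assemble statistics."""
    rows, truth = dataset_features(dataset)
    preds, branches = [], []
    for row in rows:
        label, branch = classify(
            SuctionFeatureSet(d_omega_min=row[1], dqdt_min=row[0],
                              t_dqdt_max=row[2]), thresholds)
        preds.append(label == "suction")
        branches.append(branch)
    preds = np.asarray(preds, dtype=bool)
    branches = np.asarray(branches, dtype=int)

    conf = confusion_stats(preds, truth)
    detected_suction = branches[preds & truth]
    branch1 = (float(np.mean(detected_suction == 1))
               if detected_suction.size else float("nan"))

    feature_stats: dict = {}
    comparisons: dict = {}
    for j, name in enumerate(FEATURE_NAMES):
        suction_vals = rows[truth, j]
        non_vals = rows[~truth, j]
        feature_stats[name] = {
            "suction": boxplot_stats(suction_vals),
            "non_suction": boxplot_stats(non_vals),
        }
        comparisons[name] = compare_distributions(suction_vals, non_vals)

    return ValidationReport(
        confusion={"tp": conf.tp, "fn": conf.fn, "tn": conf.tn, "fp": conf.fp},
        sensitivity=conf.sensitivity,
        specificity=conf.specificity,
        branch1_fraction=branch1,
        branch_counts={str(k): int(np.count_nonzero(branches == k))
                       for k in (0, 1, 2, 3)},
        feature_stats=feature_stats,
        comparisons=comparisons,
        thresholds={
            "thr_dqdt_min": thresholds.thr_dqdt_min,
            "thr_d_omega_min": thresholds.thr_d_omega_min,
            "thr_t_dqdt_max": thresholds.thr_t_dqdt_max,
        },
        counts={k: {"suction": v[0], "non_suction": v[1]}
                for k, v in dataset.counts().items()},
    )
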