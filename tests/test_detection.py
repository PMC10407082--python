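"""Beat segmentation, suction features and the 3-split decision tree."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from suctionsim import (Beat, SuctionFeatureSet, TreeThresholds,
                        calibrate_thresholds, classify, detect_beats,
                        extract_features)
from suctionsim.detection import (CalibrationError, ClassificationError,
                                  FeatureError, classify_many,
                                  read_telemetry, write_telemetry)

FS = 50.0


def synthetic_flow(rate_hz=78 / 60.0, duration=60.0, mean=4.0, amp=1.0):
    t = np.arange(0.0, duration, 1.0 / FS)
    return t, mean + amp * np.sin(2 * np.pi * rate_hz * t)


class TestDetectBeats:
    def test_recovers_heart_rate(self):
        t, q = synthetic_flow()
        beats = detect_beats(q)
        # 78 cycles in 60 s; boundary cycles may be lost to windowing
        assert 75 <= len(beats) + 1 <= 79
        durations = [b.duration for b in beats]
        assert np.median(durations) == pytest.approx(60 / 78.0, abs=0.02)

    def test_constant_flow_yields_no_beats(self):
        with pytest.warns(UserWarning, match="flat"):
            beats = detect_beats(np.full(500, 4.0))
        assert beats == []

    def test_windows_contiguous_half_open(self):
        _, q = synthetic_flow()
        beats = detect_beats(q)
        for a, b in zip(beats[:-1], beats[1:]):
            assert a.end_index == b.start_index

    def test_short_signal_rejected(self):
        with pytest.raises(ValueError):
            detect_beats(np.ones(100))

    def test_simulated_beat_period(self, dcm_steady):
        record, _ = dcm_steady
        beats = detect_beats(record.q_est)
        med = np.median([b.duration for b in beats])
        assert med == pytest.approx(60 / 78.0, abs=0.021)  # one sample


class TestFeatures:
    def test_analytic_slope_on_sinusoid(self):
        """dq/dt extrema of 4 + sin(2π·1.3t) are ±2π·1.3 L/min/s."""
        t = np.arange(0.0, 30.0, 1.0 / FS)
        q = 4.0 + np.sin(2 * np.pi * 1.3 * t)
        omega = np.full_like(q, 2800.0)
        beats = detect_beats(q)
        f = extract_features(beats[2], q, omega)
        assert f.dqdt_min == pytest.approx(-2 * np.pi * 1.3, rel=0.02)

    def test_constant_speed_zero_pulsatility(self):
        _, q = synthetic_flow()
        omega = np.full_like(q, 2800.0)
        b = detect_beats(q)[0]
        assert extract_features(b, q, omega).d_omega_min == 0.0

    def test_offset_invariance(self):
        _, q = synthetic_flow()
        omega = np.full_like(q, 2800.0)
        b = detect_beats(q)[1]
        f0 = extract_features(b, q, omega)
        f1 = extract_features(b, q + 2.5, omega)
        assert f1.dqdt_min == pytest.approx(f0.dqdt_min)
        assert f1.t_dqdt_max == pytest.approx(f0.t_dqdt_max)

    def test_timing_normalized(self):
        _, q = synthetic_flow()
        omega = np.full_like(q, 2800.0)
        for b in detect_beats(q):
            assert 0.0 <= extract_features(b, q, omega).t_dqdt_max < 1.0

    def test_too_short_beat(self):
        with pytest.raises(FeatureError):
            extract_features(Beat(0, 3), np.ones(10), np.ones(10))


class TestClassifier:
    def test_truth_table_equivalence(self, rng):
        """The tree equals brute-force evaluation of its three comparisons."""
        thr = TreeThresholds(-0.7, -60.0, 0.85)
        feats = np.column_stack([
            rng.uniform(-3.0, 0.5, 1000),
            rng.uniform(-200.0, 10.0, 1000),
            rng.uniform(0.0, 1.0, 1000),
        ])
        for f1, f2, f3 in feats:
            label, branch = classify(
                SuctionFeatureSet(dqdt_min=f1, d_omega_min=f2, t_dqdt_max=f3),
                thr)
            expected = (f1 >= thr.thr_dqdt_min or f2 >= thr.thr_d_omega_min
                        or f3 >= thr.thr_t_dqdt_max)
            assert (label == "suction") == expected
            if f1 >= thr.thr_dqdt_min:
                assert branch == 1
            elif f2 >= thr.thr_d_omega_min:
                assert branch == 2
            elif f3 >= thr.thr_t_dqdt_max:
                assert branch == 3
            else:
                assert branch == 0
        pred, branches = classify_many(feats, thr)
        assert pred.sum() == sum(
            classify(SuctionFeatureSet(f2, f1, f3), thr)[0] == "suction"
            for f1, f2, f3 in feats)

    def test_tie_classifies_as_suction(self):
        thr = TreeThresholds(-0.7, -60.0, 0.85)
        f = SuctionFeatureSet(dqdt_min=-0.7, d_omega_min=-100.0,
                              t_dqdt_max=0.1)
        assert classify(f, thr) == ("suction", 1)

    def test_nan_feature_rejected(self):
        with pytest.raises(ClassificationError):
            classify(SuctionFeatureSet(np.nan, -1.0, 0.5))

    def test_example_points(self):
        thr = TreeThresholds(-0.7, -60.0, 0.85)
        assert classify(SuctionFeatureSet(
            dqdt_min=-0.3, d_omega_min=-30.0, t_dqdt_max=0.97), thr) == \
            ("suction", 1)
        assert classify(SuctionFeatureSet(
            dqdt_min=-1.5, d_omega_min=-100.0, t_dqdt_max=0.60), thr) == \
            ("non_suction", 0)


class TestCalibration:
    def test_perfect_separation_gives_full_accuracy(self, rng):
        n = 60
        suction = np.column_stack([rng.uniform(-0.5, -0.2, n),
                                   rng.uniform(-40, -20, n),
                                   rng.uniform(0.9, 1.0, n)])
        non = np.column_stack([rng.uniform(-2.0, -1.0, n),
                               rng.uniform(-150, -80, n),
                               rng.uniform(0.4, 0.7, n)])
        rows = np.vstack([suction, non])
        labels = np.array([True] * n + [False] * n)
        thr = calibrate_thresholds(rows, labels)
        pred, _ = classify_many(rows, thr)
        assert np.array_equal(pred, labels)

    def test_single_class_rejected(self, rng):
        rows = rng.normal(size=(50, 3))
        with pytest.raises(CalibrationError):
            calibrate_thresholds(rows, np.ones(50, dtype=bool))

    def test_bootstrap_stability(self, protocol_dataset, rng):
        """Recalibration on a resample shifts thresholds by < 20 %."""
        from suctionsim.validation import dataset_features
        rows, labels = dataset_features(protocol_dataset)
        ref = calibrate_thresholds(rows, labels)
        idx = rng.choice(len(rows), size=len(rows), replace=True)
        boot = calibrate_thresholds(rows[idx], labels[idx])
        for name in ("thr_dqdt_min", "thr_d_omega_min"):
            a, b = getattr(ref, name), getattr(boot, name)
            assert abs(b - a) <= 0.2 * abs(a)


class TestIO:
    def test_thresholds_yaml_roundtrip(self, tmp_path):
        thr = TreeThresholds(-0.8, -55.0, 0.9)
        thr.save(tmp_path / "thr.yaml")
        assert TreeThresholds.load(tmp_path / "thr.yaml") == thr

    def test_telemetry_csv_roundtrip(self, tmp_path, dcm_steady):
        record, _ = dcm_steady
        path = tmp_path / "telemetry.csv"
        write_telemetry(path, record.t_pump, record.omega, record.i_motor,
                        record.power, record.q_est)
        tele = read_telemetry(path)
        assert np.allclose(tele["flow_est_lpm"], record.q_est, atol=1e-4)
        beats = detect_beats(tele["flow_est_lpm"])
        assert len(beats) == len(detect_beats(record.q_est))
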