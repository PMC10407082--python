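"""Confusion statistics, descriptive stats and distribution comparisons."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from suctionsim import (ValidationReport, boxplot_stats, compare_distributions,
                        confusion_stats)
from suctionsim.validation import UndefinedMetricError


class TestConfusion:
    def test_published_operating_point(self):
        """316/351 suction and 39/40 non-suction beats give 90.0%/97.5%."""
        pred = np.array([True] * 316 + [False] * 35
                        + [False] * 39 + [True] * 1)
        truth = np.array([True] * 351 + [False] * 40)
        c = confusion_stats(pred, truth)
        assert (c.tp, c.fn, c.tn, c.fp) == (316, 35, 39, 1)
        assert c.sensitivity == pytest.approx(0.900, abs=5e-4)
        assert c.specificity == pytest.approx(0.975, abs=5e-4)

    def test_perfect_prediction(self):
        truth = np.array([True, False, True, False])
        c = confusion_stats(truth, truth)
        assert c.sensitivity == 1.0 and c.specificity == 1.0

    def test_all_positive_prediction(self):
        truth = np.array([True, True, False, False])
        c = confusion_stats(np.ones(4, bool), truth)
        assert c.sensitivity == 1.0 and c.specificity == 0.0

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.tuples(st.booleans(), st.booleans()),
                    min_size=4, max_size=60))
    def test_matches_brute_force_counting(self, pairs):
        pred = np.array([p for p, _ in pairs])
        truth = np.array([t for _, t in pairs])
        if truth.all() or not truth.any():
            with pytest.raises(UndefinedMetricError):
                confusion_stats(pred, truth)
            return
        c = confusion_stats(pred, truth)
        tp = sum(1 for p, t in pairs if p and t)
        tn = sum(1 for p, t in pairs if not p and not t)
        assert c.tp == tp and c.tn == tn
        assert c.sensitivity == tp / truth.sum()
        assert c.specificity == tn / (~truth).sum()

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            confusion_stats([True], [True, False])


class TestBoxplotStats:
    def test_small_example(self):
        s = boxplot_stats([1, 2, 3, 4, 5])
        assert (s["median"], s["q1"], s["q3"], s["min"], s["max"]) == \
            (3, 2, 4, 1, 5)

    def test_constant_vector(self):
        s = boxplot_stats([7.0] * 10)
        assert len({s["median"], s["q1"], s["q3"], s["min"], s["max"]}) == 1

    def test_permutation_invariance(self, rng):
        x = rng.normal(size=101)
        a = boxplot_stats(x)
        b = boxplot_stats(rng.permutation(x))
        assert a == b

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            boxplot_stats([])


class TestCompareDistributions:
    def test_identical_samples_not_significant(self):
        x = np.arange(20.0)
        res = compare_distributions(x, x)
        assert res["p"] > 0.9
        if res["test"] == "mann-whitney":
            assert res["statistic"] == pytest.approx(len(x) ** 2 / 2)

    def test_normal_samples_take_t_test_path(self, rng):
        a, b = rng.normal(size=200), rng.normal(size=200)
        res = compare_distributions(a, b)
        assert res["test"] == "t-test"
        assert res["shapiro_p_a"] > 0.05 and res["shapiro_p_b"] > 0.05

    def test_skewed_samples_take_mann_whitney_path(self, rng):
        a = rng.exponential(size=200) ** 3
        b = rng.exponential(size=200) ** 3
        assert compare_distributions(a, b)["test"] == "mann-whitney"

    def test_gross_separation_is_significant(self, rng):
        a = rng.normal(0.0, 1.0, 100)
        b = rng.normal(5.0, 1.0, 100)
        assert compare_distributions(a, b)["p"] < 1e-3

    def test_zero_variance_falls_back_with_warning(self):
        with pytest.warns(UserWarning, match="zero-variance"):
            res = compare_distributions([1.0] * 10, [1.0, 2.0, 3.0, 4.0])
        assert res["test"] == "mann-whitney"

    def test_minimum_sample_size(self):
        with pytest.raises(ValueError):
            compare_distributions([1.0, 2.0], [1.0, 2.0, 3.0])


class TestReport:
    def test_json_roundtrip(self, protocol_report, tmp_path):
        path = tmp_path / "report.json"
        protocol_report.to_json(path)
        loaded = ValidationReport.from_json(path)
        assert loaded == protocol_report

    def test_report_invariants(self, protocol_report):
        r = protocol_report
        assert 0.0 <= r.sensitivity <= 1.0
        assert 0.0 <= r.specificity <= 1.0
        c = r.confusion
        assert r.sensitivity == c["tp"] / (c["tp"] + c["fn"])
        for feat in r.feature_stats.values():
            for cls in feat.values():
                assert cls["q1"] <= cls["median"] <= cls["q3"]
                assert cls["min"] <= cls["q1"] and cls["q3"] <= cls["max"]

    def test_reported_tests_are_nonparametric_on_skewed_features(
            self, protocol_report):
        # suction features are far from normal; the pipeline must report
        # which comparison path was taken
        for res in protocol_report.comparisons.values():
            assert res["test"] in ("t-test", "mann-whitney")
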