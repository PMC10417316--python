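"""Error metrics, standards graders, and Bland-Altman agreement."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ppgbp import (
    InvalidArgumentError,
    bland_altman,
    cumulative_percentage,
    evaluation_report,
    grade_aami,
    grade_bhs,
    grade_ieee,
    mad,
    mean_error,
    sd_of_errors,
)


class TestMetrics:
    def test_mad_examples(self):
        assert mad([1.0, 2.0, 3.0], [0.0, 0.0, 0.0]) == pytest.approx(2.0)
        assert mad([5.0, 5.0], [5.0, 5.0]) == 0.0
        assert mad([1.0, -1.0], [0.0, 0.0]) == pytest.approx(1.0)

    def test_mean_error_sign_convention_reference_minus_prediction(self):
        assert mean_error([1.0, -1.0], [0.0, 0.0]) == pytest.approx(0.0)
        assert mean_error([0.0, 0.0], [2.0, 2.0]) == pytest.approx(2.0)
        with pytest.raises(InvalidArgumentError):
            mean_error([], [])

    def test_sd_of_errors_is_sample_sd(self):
        assert sd_of_errors([1.0, 2.0, 3.0]) == pytest.approx(1.0)
        assert sd_of_errors([4.0, 4.0, 4.0]) == 0.0
        with pytest.raises(InvalidArgumentError):
            sd_of_errors([1.0])

    def test_cumulative_percentage(self):
        d = [1.0, 6.0, 20.0]
        assert cumulative_percentage(d, 5) == pytest.approx(100 / 3)
        assert cumulative_percentage(d, np.inf) == 100.0
        assert (
            cumulative_percentage(d, 5)
            <= cumulative_percentage(d, 10)
            <= cumulative_percentage(d, 15)
        )

    def test_metrics_match_naive_recomputation_on_random_vectors(self, rng):
        p = rng.normal(120, 10, size=200)
        r = p + rng.normal(0, 5, size=200)
        d = r - p
        assert mad(p, r) == pytest.approx(sum(abs(x) for x in d) / len(d))
        assert mean_error(p, r) == pytest.approx(sum(d) / len(d))
        mean_d = sum(d) / len(d)
        naive_sd = (sum((x - mean_d) ** 2 for x in d) / (len(d) - 1)) ** 0.5
        assert sd_of_errors(d) == pytest.approx(naive_sd)
        for thr in (5, 10, 15):
            assert cumulative_percentage(d, thr) == pytest.approx(
                100 * sum(abs(x) <= thr for x in d) / len(d)
            )


class TestGraders:
    @pytest.mark.parametrize(
        "mad_value,grade",
        [(2.89, "A"), (5.0, "A"), (5.34, "B"), (6.0, "B"), (6.5, "C"), (7.0, "C"), (7.53, "D")],
    )
    def test_ieee_bands(self, mad_value, grade):
        assert grade_ieee(mad_value) == grade

    @pytest.mark.parametrize(
        "cps,grade",
        [
            ((81.70, 98.28, 100.0), "A"),
            ((63.4, 85.9, 92.78), "B"),   # CP15 < 95 blocks A
            ((45.14, 72.02, 86.0), "C"),
            ((30.92, 53.07, 67.37), "D"),
            ((60.0, 85.0, 95.0), "A"),    # inclusive boundaries
        ],
    )
    def test_bhs_bands(self, cps, grade):
        assert grade_bhs(*cps) == grade

    @pytest.mark.parametrize(
        "me,sd,passed",
        [(0.13, 7.04, True), (-0.49, 20.7, False), (5.0, 8.0, True), (-5.0, 8.0, True),
         (5.1, 1.0, False), (0.0, 8.1, False)],
    )
    def test_aami_uses_absolute_me_and_inclusive_limits(self, me, sd, passed):
        assert grade_aami(me, sd) is passed

    def test_published_grading_truth_table(self):
        """Re-grading the three models' printed per-target statistics
        reproduces their published grades; the one printed IEEE grade that
        contradicts the IEEE band definition (MAD 7.53 listed as C) is
        graded by the band definition instead (D)."""
        rows = [
            # (mad, me, sd, cp5, cp10, cp15, ieee, bhs, aami_pass)
            (14.281, -0.49, 20.7, 30.92, 53.07, 67.37, "D", "D", False),   # LSTM SBP
            (7.53, -0.21, 10.01, 45.14, 72.02, 86.0, "D", "C", False),     # LSTM DBP (doc'd exception)
            (26.94, -0.93, 19.01, 27.0, 52.5, 68.70, "D", "D", False),     # LSTM-AE SBP
            (5.71, -0.56, 7.67, 56.67, 83.8, 92.98, "B", "B", True),       # LSTM-AE DBP
            (5.34, 0.13, 7.04, 63.4, 85.9, 92.78, "B", "B", True),         # CNN-LSTM SBP
            (2.89, 0.48, 3.79, 81.70, 98.28, 100.0, "A", "A", True),       # CNN-LSTM DBP
        ]
        for mad_v, me, sd, cp5, cp10, cp15, ieee, bhs, aami in rows:
            assert grade_ieee(mad_v) == ieee
            assert grade_bhs(cp5, cp10, cp15) == bhs
            assert grade_aami(me, sd) is aami

    @given(st.lists(st.floats(-30, 30), min_size=5, max_size=50),
           st.floats(0.1, 0.9))
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_shrinking_errors_never_worsens_any_grade(self, errors, shrink):
        errors = np.asarray(errors)
        ref = np.full_like(errors, 100.0)
        pred_big = ref - errors
        pred_small = ref - shrink * errors

        def grades(pred):
            rep = evaluation_report(pred, ref)
            return rep.ieee_grade, rep.bhs_grade, rep.aami_pass

        g_big, g_small = grades(pred_big), grades(pred_small)
        assert g_small[0] <= g_big[0]           # letter grades order A < B < C < D
        assert g_small[1] <= g_big[1]
        assert g_small[2] >= g_big[2]           # pass (True) never degrades to fail


class TestBlandAltman:
    def test_identical_vectors(self):
        center, lower, upper = bland_altman([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert (center, lower, upper) == (0.0, 0.0, 0.0)

    def test_two_point_limits(self):
        center, lower, upper = bland_altman([1.0, -1.0], [0.0, 0.0])
        assert center == pytest.approx(0.0)
        assert upper == pytest.approx(1.96 * np.sqrt(2.0))
        assert lower == pytest.approx(-1.96 * np.sqrt(2.0))

    def test_translation_equivariance(self, rng):
        p = rng.normal(size=30)
        r = rng.normal(size=30)
        base = bland_altman(p, r)
        shifted = bland_altman(p + 3.0, r)
        np.testing.assert_allclose(np.array(shifted), np.array(base) - 3.0, atol=1e-12)


class TestReport:
    def test_zero_error_report_gets_top_grades(self):
        report = evaluation_report(np.full(10, 120.0), np.full(10, 120.0))
        assert report.mad == 0.0
        assert report.ieee_grade == "A"
        assert report.bhs_grade == "A"
        assert report.aami_pass is True
        assert report.n == 10

    def test_report_fields_equal_individual_operations(self, rng):
        p = rng.normal(120, 15, size=100)
        r = p + rng.normal(0, 6, size=100)
        d = r - p
        report = evaluation_report(p, r)
        assert report.mad == pytest.approx(mad(p, r))
        assert report.me == pytest.approx(mean_error(p, r))
        assert report.sd == pytest.approx(sd_of_errors(d))
        assert report.cp5 == pytest.approx(cumulative_percentage(d, 5))
        assert report.ieee_grade == grade_ieee(report.mad)
        assert report.bhs_grade == grade_bhs(report.cp5, report.cp10, report.cp15)
        assert report.aami_pass == grade_aami(report.me, report.sd)
        ba = bland_altman(p, r)
        assert report.bland_altman_mean == pytest.approx(ba[0])

    def test_json_round_trip(self, tmp_path, rng):
        import json

        p = rng.normal(120, 15, size=20)
        r = p + rng.normal(0, 4, size=20)
        report = evaluation_report(p, r)
        report.to_json(tmp_path / "report.json")
        loaded = json.loads((tmp_path / "report.json").read_text())
        assert loaded["n"] == 20
        assert loaded["ieee_grade"] == report.ieee_grade
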