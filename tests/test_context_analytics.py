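import numpy as np
import pandas as pd
import pytest

from rmatrace.context_analytics import (
    CalibrationModel,
    ClassifierThresholds,
    EstimationError,
    ExtrapolationWarning,
    GrowthSeries,
    NRF2Status,
    accumulate_cvh,
    calibrate_and_quantify,
    cell_volume_hours,
    classify_nrf2,
    fit_calibration,
    fit_fluxes,
    flux_fit,
    labeled_fraction_with_detection_rule,
    nrf2_activation_score,
    proliferation_rate,
    quintile_thresholds,
)

GENES = ["ABCC2", "ABCC3", "AKR1B10", "AKR1C1", "GCLM", "GSR", "ME1",
         "NQO1", "TXNRD1"]


class TestNRF2Score:
    def matrix(self, values_by_line):
        return pd.DataFrame(
            {g: {line: v for line, v in values_by_line.items()} for g in GENES}
        )

    def test_line_at_mean_scores_zero(self):
        expr = self.matrix({"A": 1.0, "B": 2.0, "C": 3.0})
        assert nrf2_activation_score(expr, "B") == pytest.approx(0.0)

    def test_line_one_sd_above_scores_nine(self):
        # column [0, 2, 4]: mean 2, sd (ddof=1) 2 -> the "4" line is +1 sd
        expr = self.matrix({"A": 0.0, "B": 2.0, "C": 4.0})
        assert nrf2_activation_score(expr, "C") == pytest.approx(9.0)

    def test_toy_matrix_matches_direct_zscore_sum(self):
        rng = np.random.default_rng(2)
        expr = pd.DataFrame(rng.normal(5, 2, (4, 9)),
                            index=list("ABCD"), columns=GENES)
        expected = float(
            ((expr.loc["B"] - expr.mean()) / expr.std(ddof=1)).sum()
        )
        assert nrf2_activation_score(expr, "B") == pytest.approx(expected)

    def test_translation_and_scale_invariance(self):
        rng = np.random.default_rng(3)
        expr = pd.DataFrame(rng.normal(0, 1, (5, 9)),
                            index=list("ABCDE"), columns=GENES)
        shifted = expr * 7.5 + 100.0
        for line in expr.index:
            assert nrf2_activation_score(shifted, line) == pytest.approx(
                nrf2_activation_score(expr, line)
            )

    def test_zero_sd_names_gene(self):
        expr = self.matrix({"A": 1.0, "B": 1.0})
        with pytest.raises(ValueError, match="ABCC2"):
            nrf2_activation_score(expr, "A")

    def test_missing_gene_rejected(self):
        expr = pd.DataFrame({"NQO1": {"A": 1.0, "B": 2.0}})
        with pytest.raises(KeyError):
            nrf2_activation_score(expr, "A")


class TestClassifyNRF2:
    @pytest.mark.parametrize("dependency,score,expected", [
        (-0.5, 5.0, NRF2Status.on),
        (-0.1, 5.0, NRF2Status.off),
        (-0.5, 3.0, NRF2Status.off),
        (-0.3028, 4.06, NRF2Status.off),  # strict boundaries
    ])
    def test_thresholds(self, dependency, score, expected):
        assert classify_nrf2(dependency, score) is expected

    def test_quintile_helper_recomputes_cutoffs(self):
        deps = np.linspace(-1, 0, 101)
        scores = np.linspace(0, 10, 101)
        t = quintile_thresholds(deps, scores)
        assert t.dependency_max == pytest.approx(-0.8)
        assert t.score_min == pytest.approx(8.0)


class TestCellVolumeHours:
    def test_zero_growth_limit(self):
        assert cell_volume_hours(100, 0.0, 24) == pytest.approx(2400.0)

    def test_closed_form(self):
        # N0/(k ln2) * (2^(kT) - 1) at one doubling per day
        assert cell_volume_hours(100, 1 / 24, 24) == pytest.approx(3462.47, abs=0.01)

    def test_zero_volume(self):
        assert cell_volume_hours(0, 0.5, 10) == 0.0

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            cell_volume_hours(100, 0.1, -1)

    def test_continuous_in_k_at_zero(self):
        n0, T = 100.0, 24.0
        assert abs(cell_volume_hours(n0, 1e-9, T) - n0 * T) < 1e-3 * n0 * T


class TestAccumulateCVH:
    def test_single_segment_equals_closed_form(self):
        k = 0.03
        series = GrowthSeries(times=[0.0, 24.0],
                              volumes=[50.0, 50.0 * 2 ** (k * 24)])
        acc = accumulate_cvh(series)
        assert acc[0] == 0.0
        assert acc[1] == pytest.approx(cell_volume_hours(50.0, k, 24.0))

    def test_two_flat_segments_accumulate(self):
        series = GrowthSeries(times=[0.0, 10.0, 20.0],
                              volumes=[30.0, 30.0, 30.0])
        assert accumulate_cvh(series)[2] == pytest.approx(2 * 30.0 * 10.0)

    def test_three_segment_hand_computation(self):
        # volumes double over the first 12 h, grow 1.5x over the next 12,
        # then stay flat; accumulate interval integrals step by step
        times = [0.0, 12.0, 24.0, 36.0]
        vols = [10.0, 20.0, 30.0, 30.0]
        expected = 0.0
        steps = []
        for (t0, t1, v0, v1) in zip(times, times[1:], vols, vols[1:]):
            k = np.log2(v1 / v0) / (t1 - t0)
            expected += cell_volume_hours(v0, k, t1 - t0)
            steps.append(expected)
        acc = accumulate_cvh(GrowthSeries(times=times, volumes=vols))
        assert acc[1:] == pytest.approx(steps)

    def test_replicate_wells_couple_through_running_mean(self):
        # two wells with different growth: well accumulation starts from the
        # mean of the previous timepoint, not the well's own history
        times = [0.0, 10.0, 20.0]
        vols = np.array([[10.0, 10.0], [10.0, 20.0], [10.0, 20.0]])
        acc = accumulate_cvh(GrowthSeries(times=times, volumes=vols))
        mean_first = acc[1].mean()
        v0 = vols[1].mean()  # 15 = averaged starting volume of segment 2
        k_w0 = np.log2(10.0 / v0) / 10.0
        assert acc[2, 0] == pytest.approx(
            mean_first + cell_volume_hours(v0, k_w0, 10.0)
        )

    def test_non_monotone_times_rejected(self):
        with pytest.raises(ValueError):
            GrowthSeries(times=[0.0, 5.0, 5.0], volumes=[1.0, 2.0, 3.0])


class TestFluxFit:
    def test_exact_recovery_without_noise(self):
        cvh = np.array([0.0, 50.0, 100.0, 150.0, 200.0])
        moles = 4e-6 - 1e-15 * cvh
        est = flux_fit(cvh, moles)
        assert est.slope == pytest.approx(-1e-15)
        assert est.points_used == 5

    def test_overgrowth_exclusion(self):
        cvh = np.array([0.0, 100.0, 200.0, 310.0])
        moles = 4e-6 - 1e-15 * cvh
        est = flux_fit(cvh, moles)
        assert (3, "cvh_overgrowth") in est.points_excluded
        assert est.points_used == 3

    def test_depletion_exclusion(self):
        cvh = np.array([0.0, 100.0, 200.0, 290.0])
        moles = np.array([1e-6, 0.5e-6, 0.3e-6, 0.08e-6])  # 8% of initial
        est = flux_fit(cvh, moles)
        assert (3, "depletion") in est.points_excluded

    def test_too_few_points_raises(self):
        with pytest.raises(EstimationError):
            flux_fit([0.0, 310.0, 320.0], [1e-6, 1e-6, 1e-6])

    def test_linked_metabolite_exclusion_propagates(self):
        times = [0.0, 12.0, 24.0, 36.0]
        series = GrowthSeries(
            times=times, volumes=[10.0] * 4,
            moles={
                "cystine": np.array([1e-6, 0.5e-6, 0.2e-6, 0.05e-6]),
                "glutamate": np.array([0.0, 1e-7, 2e-7, 3e-7]) + 1e-6,
            },
        )
        fits = fit_fluxes(series, links={"cystine": ["glutamate"]})
        reasons = dict(fits["glutamate"].points_excluded)
        assert reasons.get(3, "").startswith("linked_depletion")

    def test_noisy_estimator_bias_below_stderr(self):
        """OLS slope bias over replicate noisy series (n=9, sigma=5% of
        range) stays below the typical reported standard error."""
        rng = np.random.default_rng(17)
        cvh = np.linspace(0.0, 280.0, 9)
        truth = -1e-15
        moles = 4e-6 + truth * cvh
        slopes, stderrs = [], []
        for _ in range(40):
            noisy = moles + rng.normal(0, 0.05 * np.ptp(moles), 9)
            est = flux_fit(cvh, noisy)
            slopes.append(est.slope)
            stderrs.append(est.stderr)
        bias = abs(np.mean(slopes) - truth)
        assert bias < np.mean(stderrs)


class TestProliferationRate:
    @pytest.mark.parametrize("n0,n1,days,expected", [
        (1e5, 4e5, 2, 1.0),
        (1e5, 1e5, 4, 0.0),
        (2e5, 1e5, 1, -1.0),
    ])
    def test_formula(self, n0, n1, days, expected):
        assert proliferation_rate(n0, n1, days) == pytest.approx(expected)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            proliferation_rate(0, 1e5, 2)


class TestCalibration:
    def test_linear_standards_select_linear(self):
        standards = [(0.5, 1.0), (1.0, 2.0), (2.0, 4.0), (4.0, 8.0)]
        assert fit_calibration(standards).model is CalibrationModel.linear
        assert calibrate_and_quantify(standards, 1.0) == pytest.approx(2.0)

    def test_square_law_selects_power(self):
        standards = [(1.0, 1.0), (2.0, 4.0), (3.0, 9.0), (4.0, 16.0)]
        curve = fit_calibration(standards)
        assert curve.model is CalibrationModel.power
        assert calibrate_and_quantify(standards, 3.0) == pytest.approx(9.0)

    def test_quadratic_with_offset_selected(self):
        standards = [(r, 1.0 + 2.0 * r + 0.5 * r * r) for r in (0.5, 1, 2, 3, 5)]
        assert fit_calibration(standards).model is CalibrationModel.quadratic

    def test_two_standards_rejected(self):
        with pytest.raises(ValueError):
            fit_calibration([(1.0, 1.0), (2.0, 2.0)])

    def test_extrapolation_warns(self):
        standards = [(1.0, 2.0), (2.0, 4.0), (4.0, 8.0)]
        with pytest.warns(ExtrapolationWarning):
            calibrate_and_quantify(standards, 100.0)


class TestLabeledFractionRule:
    def test_fraction(self):
        assert labeled_fraction_with_detection_rule(
            [900.0, 0.0, 0.0, 100.0]
        ) == pytest.approx(0.1)

    @pytest.mark.parametrize("areas", [
        [900.0, 0.0, 0.0, 0.0],  # M+3 undetected
        [0.0, 0.0, 0.0, 100.0],  # M+0 undetected
    ])
    def test_detection_rule_excludes(self, areas):
        assert labeled_fraction_with_detection_rule(areas) is None

    def test_middle_isotopologues_enter_denominator(self):
        assert labeled_fraction_with_detection_rule(
            [700.0, 100.0, 100.0, 100.0]
        ) == pytest.approx(0.1)
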