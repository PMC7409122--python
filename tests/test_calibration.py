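"""Weighted calibration: fit, inverse prediction, acceptance rules, oracles."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from mobiquant.calibration import (
    CalibrationModel,
    compute_response,
    evaluate_calibration,
    fit_weighted_linear,
)
from mobiquant.design import CAL_LEVELS_NG_PER_ML

LEVELS = np.array(CAL_LEVELS_NG_PER_ML)


def _normal_equation_wls(x, y, w):
    """Independent closed-form weighted least squares (2x2 normal equations)."""
    sw, swx = w.sum(), (w * x).sum()
    swxx, swy, swxy = (w * x * x).sum(), (w * y).sum(), (w * x * y).sum()
    det = sw * swxx - swx**2
    a = (swxx * swy - swx * swxy) / det
    b = (sw * swxy - swx * swy) / det
    ybar = swy / sw
    ss_res = (w * (y - a - b * x) ** 2).sum()
    ss_tot = (w * (y - ybar) ** 2).sum()
    return a, b, 1.0 - ss_res / ss_tot


class TestComputeResponse:
    @pytest.mark.parametrize(
        "analyte,is_area,expected", [(0, 5000, 0.0), (5000, 5000, 1.0), (1234, 617, 2.0)]
    )
    def test_ratio(self, analyte, is_area, expected):
        assert compute_response(analyte, is_area).y == pytest.approx(expected)

    def test_zero_is_area_flags_invalid(self):
        resp = compute_response(100.0, 0.0)
        assert not resp.valid and np.isnan(resp.y)

    def test_negative_area_rejected(self):
        with pytest.raises(ValueError):
            compute_response(-1.0, 10.0)


class TestFit:
    def test_exact_line_through_origin(self):
        y = 0.002 * LEVELS
        fit = fit_weighted_linear(list(zip(LEVELS, y)))
        assert fit.intercept == pytest.approx(0.0, abs=1e-12)
        assert fit.slope == pytest.approx(0.002, rel=1e-12)
        assert fit.r2 == pytest.approx(1.0, abs=1e-12)

    def test_two_points_interpolated_exactly(self):
        fit = fit_weighted_linear([(5.0, 1.0), (1000.0, 200.0)])
        assert fit.predict(5.0) == pytest.approx(1.0)
        assert fit.predict(1000.0) == pytest.approx(200.0)
        assert fit.r2 == pytest.approx(1.0)

    def test_inverse_variance_weighting_downweights_top_level_outlier(self):
        y = 0.002 * LEVELS
        y_out = y.copy()
        y_out[-1] *= 1.5  # +50% outlier at x = 1000
        weighted = CalibrationModel(LEVELS, y_out, weighting="1/x^2").fit()
        unweighted = CalibrationModel(LEVELS, y_out, weighting="none").fit()
        assert abs(weighted.slope - 0.002) < abs(unweighted.slope - 0.002)

    def test_matches_normal_equation_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            x = np.repeat(LEVELS, 2)
            y = 0.001 + 0.003 * x * rng.lognormal(0, 0.05, len(x))
            fit = CalibrationModel(x, y).fit()
            a, b, r2 = _normal_equation_wls(x, y, 1.0 / x**2)
            assert fit.intercept == pytest.approx(a, rel=1e-9, abs=1e-12)
            assert fit.slope == pytest.approx(b, rel=1e-9)
            assert fit.r2 == pytest.approx(r2, rel=1e-9)

    def test_zero_concentration_points_excluded(self):
        x = np.array([0.0, 0.0, 5.0, 10.0, 100.0])
        y = 0.01 * x
        model = CalibrationModel(x, y)
        assert model.n_excluded == 2
        assert len(model.x) == 3

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            CalibrationModel([5.0, 5.0, 5.0], [1.0, 1.1, 0.9])
        with pytest.raises(ValueError, match="weighting"):
            CalibrationModel([5.0, 10.0], [1.0, 2.0], weighting="1/x^3")

    def test_level_means_option(self):
        x = np.array([5.0, 5.0, 100.0, 100.0])
        y = np.array([1.0, 3.0, 40.0, 60.0])
        fit = CalibrationModel(x, y, use_level_means=True).fit()
        assert fit.n == 2
        assert fit.predict(5.0) == pytest.approx(2.0)


class TestBackCalculation:
    @given(x=st.floats(0.1, 5000.0, allow_nan=False))
    def test_round_trip_exact(self, x):
        fit = fit_weighted_linear([(5.0, 1.01), (1000.0, 200.01)])
        assert fit.back_calculate(fit.predict(x)) == pytest.approx(x, rel=1e-9)

    def test_intercept_maps_to_zero_and_negative_reported(self):
        fit = fit_weighted_linear([(5.0, 1.0 + 0.5), (1000.0, 200.0 + 0.5)])
        assert fit.back_calculate(fit.intercept) == pytest.approx(0.0, abs=1e-9)
        assert fit.back_calculate(fit.intercept + 2 * fit.slope) == pytest.approx(2.0)
        assert fit.back_calculate(0.0) < 0  # below-intercept responses stay negative

    def test_non_positive_slope_rejected(self):
        fit = fit_weighted_linear([(5.0, 10.0), (1000.0, 1.0)])  # negative slope
        with pytest.raises(ValueError, match="slope"):
            fit.back_calculate(1.0)


class TestAcceptance:
    def _fit_with_level_biases(self, biases):
        """One replicate per level with the requested per-level bias (%)."""
        y = 0.002 * LEVELS * (1 + np.asarray(biases) / 100.0)
        return CalibrationModel(LEVELS, y).fit()

    def test_noiseless_curve_fully_accepted(self):
        acc = self._fit_with_level_biases(np.zeros(8)).evaluate(lloq_conc=5.0)
        assert acc.verdict and acc.accepted_levels == 8
        assert acc.r2_ok

    def test_single_bad_level_tolerated(self):
        # +30% on CAL20 only: 7/8 = 87.5% > 75% and >= 6 levels -> accepted.
        biases = np.zeros(8)
        biases[2] = 30.0
        fit = self._fit_with_level_biases(biases)
        acc = evaluate_calibration(fit, lloq_conc=5.0)
        # the fit itself shifts slightly; the deliberately biased level must fail
        assert not [r for r in acc.per_level if r["level"] == 20.0][0]["accepted"]
        assert acc.accepted_levels >= 7
        assert acc.verdict

    def test_three_bad_levels_reject_curve(self):
        biases = np.zeros(8)
        biases[[2, 4, 6]] = 40.0
        acc = self._fit_with_level_biases(biases).evaluate(lloq_conc=5.0)
        assert acc.accepted_levels <= 5
        assert not acc.verdict

    def test_summary_is_human_readable(self):
        fit = self._fit_with_level_biases(np.zeros(8))
        text = fit.summary()
        assert "slope" in text and "r^2" in text and "accepted" in text


class TestParameterRecovery:
    def test_slope_recovered_within_5pct_under_5pct_replicate_noise(
        self, instrument_w, noiseless_config
    ):
        """Fitting generator batches with 5% replicate CV recovers the noiseless
        response slope within 5% (median over seeds)."""
        from mobiquant.campaign import extract_features
        from mobiquant.design import SampleRole, build_batch_layout
        from mobiquant.simulate import SignalModel, simulate_batch

        layout = [r for r in build_batch_layout("validation") if r.role is SampleRole.CAL]

        def fitted_slope(signal, seed):
            acqs = simulate_batch(layout, instrument_w, signal, seed=seed)
            feat = extract_features(acqs, layout, noiseless_config)
            return CalibrationModel(
                feat["nominal_conc_ng_per_mL"].to_numpy(), feat["response"].to_numpy()
            ).fit().slope

        truth = fitted_slope(noiseless_config.signal, seed=0)
        noisy = SignalModel(replicate_cv=0.05, spot_heterogeneity=0.0, baseline_noise=0.0)
        errors = [abs(fitted_slope(noisy, seed) / truth - 1.0) for seed in range(15)]
        assert np.median(errors) < 0.05
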