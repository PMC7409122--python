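"""Validation statistics: precision/accuracy, blanks, recovery, matrix factor, report."""

import numpy as np
import pytest

from mobiquant.campaign import extract_features
from mobiquant.config import PipelineConfig
from mobiquant.design import QC_LEVELS_NG_PER_ML, build_batch_layout
from mobiquant.simulate import SignalModel, simulate_batch
from mobiquant.validation import (
    AcceptanceLimits,
    PrecisionAccuracy,
    Scope,
    build_validation_report,
    carryover_check,
    check_acceptance,
    matrix_factor,
    mean_normalized_matrix_factor,
    precision_accuracy,
    recovery,
    specificity_check,
)


class TestPrecisionAccuracy:
    @pytest.mark.parametrize(
        "measured,nominal,bias,cv",
        [
            ([10, 10, 10], 10, 0.0, 0.0),
            ([8, 12], 10, 0.0, 28.284271),
            ([11, 11, 11], 10, 10.0, 0.0),
        ],
    )
    def test_worked_examples(self, measured, nominal, bias, cv):
        pa = precision_accuracy(measured, nominal)
        assert pa.bias_pct == pytest.approx(bias, abs=1e-6)
        assert pa.cv_pct == pytest.approx(cv, abs=1e-4)

    def test_matches_brute_force_recomputation(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            vals = rng.lognormal(np.log(50), 0.1, size=8)
            pa = precision_accuracy(vals, 50.0, Scope.BATCH_TO_BATCH)
            mean = sum(vals) / len(vals)
            sd = (sum((v - mean) ** 2 for v in vals) / (len(vals) - 1)) ** 0.5
            assert pa.mean_measured == pytest.approx(mean, rel=1e-12)
            assert pa.cv_pct == pytest.approx(100 * sd / mean, rel=1e-12)
            assert pa.bias_pct == pytest.approx(100 * (mean - 50) / 50, rel=1e-12)

    def test_preconditions(self):
        with pytest.raises(ValueError, match="n >= 2"):
            precision_accuracy([10.0], 10.0)
        with pytest.raises(ValueError, match="nominal"):
            precision_accuracy([10.0, 11.0], 0.0)


class TestAcceptanceLimits:
    def _pa(self, cv, bias, level=400.0):
        return PrecisionAccuracy(level=level, n=8, mean_measured=level, cv_pct=cv,
                                 bias_pct=bias)

    def test_reported_lloq_values_pass(self):
        # the assay's reported LLOQ figures: CV 12.6%, bias -3.4%
        assert check_acceptance(self._pa(12.6, -3.4, 5.0), is_lloq=True)

    def test_cv_limit_is_strict(self):
        assert not check_acceptance(self._pa(15.0, 0.0))
        assert check_acceptance(self._pa(14.99, 0.0))

    def test_bias_limit_is_inclusive_but_20_1_fails_at_lloq(self):
        assert check_acceptance(self._pa(5.0, 15.0))  # inclusive at the limit
        assert not check_acceptance(self._pa(5.0, -20.1, 5.0), is_lloq=True)

    def test_configurable_conventions(self):
        limits = AcceptanceLimits(cv_strict=False, bias_strict=True)
        assert check_acceptance(self._pa(15.0, 0.0), limits=limits)
        assert not check_acceptance(self._pa(0.0, 15.0), limits=limits)


class TestBlankChecks:
    def test_all_zero_blanks_pass(self):
        res = specificity_check([0] * 6, [0] * 6, 100.0, 5000.0)
        assert res.verdict and res.max_analyte_ratio_pct == 0.0

    def test_one_contaminated_source_fails(self):
        res = specificity_check([0, 0, 25.0, 0, 0, 0], [0] * 6, 100.0, 5000.0)
        assert not res.verdict and res.max_analyte_ratio_pct == 25.0

    def test_is_contamination_just_below_limit_passes(self):
        res = specificity_check([0] * 6, [5000 * 0.049] * 6, 100.0, 5000.0)
        assert res.verdict

    def test_few_sources_warn_but_still_verdict(self):
        res = specificity_check([0] * 3, [0] * 3, 100.0, 5000.0)
        assert res.verdict and "3 blank sources" in res.warning

    def test_carryover_thresholds(self):
        ref = 100.0
        assert carryover_check([0.0, 0.0], [0.0, 0.0], ref, 5000.0).verdict
        assert carryover_check([17.0, 17.0], [0.0, 0.0], ref, 5000.0).verdict  # < 20%
        assert not carryover_check([21.0, 21.0], [0.0, 0.0], ref, 5000.0).verdict


class TestRecovery:
    def test_identical_series_gives_100(self):
        res = recovery([1.0, 1.1, 0.9, 1.0], [1.0, 1.1, 0.9, 1.0], 15.0)
        assert res.recovery_pct == pytest.approx(100.0)
        assert res.cv_pct == pytest.approx(0.0, abs=1e-9)

    def test_empty_series_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            recovery([1.0], [], 15.0)
        with pytest.raises(ValueError, match="zero"):
            recovery([1.0], [0.0], 15.0)

    def test_recovers_generator_extraction_fraction(self, instrument_w, default_config):
        """Noiseless DIL/REC simulation returns the generator's extraction
        recovery through the IS-normalized estimator."""
        for frac in (0.536, 1.0):
            signal = SignalModel(replicate_cv=0.0, spot_heterogeneity=0.0,
                                 baseline_noise=0.0, extraction_recovery=frac,
                                 interferent_area=0.0)
            layout = build_batch_layout("recovery", batch_id="R")
            acqs = simulate_batch(layout, instrument_w, signal, seed=0)
            feat = extract_features(acqs, layout, default_config)
            for lvl in ("LQC", "MQC", "HQC"):
                dil = feat[(feat.level == lvl) & (feat.role == "QC_DIL")].response
                rec = feat[(feat.level == lvl) & (feat.role == "QC_REC")].response
                res = recovery(dil.to_numpy(), rec.to_numpy(), QC_LEVELS_NG_PER_ML[lvl])
                assert res.recovery_pct == pytest.approx(100.0 * frac, rel=1e-9)


class TestMatrixFactor:
    def test_identical_series_gives_100(self):
        pairs = [(100.0, 200.0), (110.0, 220.0), (90.0, 180.0)]
        res = matrix_factor(pairs, pairs, 15.0)
        assert res.mf_analyte_pct == pytest.approx(100.0)
        assert res.mf_normalized_pct == pytest.approx(100.0)

    def test_reported_per_level_mfs_average_to_100(self):
        """The assay's per-level IS-normalized MFs {102.5, 98.1, 99.4}% mean 100.0%."""
        results = []
        for lvl, mf in ((15.0, 102.5), (400.0, 98.1), (800.0, 99.4)):
            pairs_mat = [(mf, 100.0)] * 4
            pairs_el = [(100.0, 100.0)] * 4
            results.append(matrix_factor(pairs_mat, pairs_el, lvl))
        assert mean_normalized_matrix_factor(results) == pytest.approx(100.0, abs=1e-9)

    def test_co_suppression_cancels(self):
        mat = [(80.0, 160.0)] * 4  # both compounds suppressed 20%
        el = [(100.0, 200.0)] * 4
        res = matrix_factor(mat, el, 400.0)
        assert res.mf_analyte_pct == pytest.approx(80.0)
        assert res.mf_normalized_pct == pytest.approx(100.0)

    def test_recovers_generator_matrix_ratio(self, instrument_w, default_config):
        signal = SignalModel(replicate_cv=0.0, spot_heterogeneity=0.0, baseline_noise=0.0,
                             matrix_factor_analyte=0.9, matrix_factor_is=1.0,
                             interferent_area=0.0)
        layout = build_batch_layout("matrix_effect", batch_id="M")
        acqs = simulate_batch(layout, instrument_w, signal, seed=0)
        feat = extract_features(acqs, layout, default_config)
        for lvl in ("LQC", "MQC", "HQC"):
            mat = feat[(feat.level == lvl) & (feat.role == "QC_MAT")][
                ["analyte_moba", "is_moba"]].to_numpy()
            el = feat[(feat.level == lvl) & (feat.role == "QC_EL")][
                ["analyte_moba", "is_moba"]].to_numpy()
            res = matrix_factor(mat, el, QC_LEVELS_NG_PER_ML[lvl])
            assert res.mf_normalized_pct == pytest.approx(90.0, rel=1e-6)

    def test_zero_eluent_mean_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            matrix_factor([(1.0, 1.0)], [(0.0, 1.0)], 15.0)


class TestReport:
    def _sections(self):
        return dict(
            sensitivity={"pass": True}, calibration={"pass": True}, qc={"pass": True},
            specificity={"pass": True}, carryover={"pass": True},
            freeze_thaw={"pass": True},
            recovery_results={"pass": True}, matrix_results={"pass": True},
        )

    def test_all_pass_is_validated(self):
        report = build_validation_report(**self._sections())
        assert report.overall_verdict == "validated"

    def test_missing_section_marks_incomplete(self):
        sections = self._sections()
        sections["carryover"] = None
        report = build_validation_report(**sections)
        assert report.overall_verdict == "incomplete"
        assert report.to_dict()["sections"]["carryover"] is None

    def test_failed_section_dominates(self):
        sections = self._sections()
        sections["qc"] = {"pass": False}
        sections["carryover"] = None
        assert build_validation_report(**sections).overall_verdict == "failed"

    def test_report_round_trips_through_json(self):
        from mobiquant.validation import ValidationReport

        report = build_validation_report(**self._sections())
        clone = ValidationReport.from_json(report.to_json())
        assert clone.to_dict() == report.to_dict()
        assert "Overall: validated" in report.to_markdown()
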