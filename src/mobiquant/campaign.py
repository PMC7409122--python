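"""End-to-end validation campaign: simulate -> extract -> calibrate -> validate.

A campaign reproduces the assay's validation design: four batches on
four days, each with quadruplicate blanks/calibrators and eight
replicates of the four QC levels; freeze/thaw QCs ride along in the
third batch and carry-over blanks in the fourth; a six-source blank
panel, and the paired recovery (QC DIL / QC REC) and matrix-effect
(QC MAT / QC EL) series complete the design.  Everything is a pure
function of (config, seed): rerunning writes byte-identical artifacts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .calibration import CalibrationModel, CalibrationResult, compute_response
from .config import PipelineConfig
from .design import (
    QC_LEVELS_NG_PER_ML,
    RECOVERY_QC_LEVELS,
    SampleRecord,
    SampleRole,
    build_batch_layout,
    freeze_thaw_records,
    layout_to_dataframe,
)
from .mobilogram import massi, moba
from .simulate import Acquisition, simulate_batch
from .validation import (
    AcceptanceLimits,
    Scope,
    build_validation_report,
    carryover_check,
    check_acceptance,
    matrix_factor,
    precision_accuracy,
    recovery,
    specificity_check,
)

__all__ = ["CampaignResult", "run_campaign", "extract_features"]

_QC_ROLES = (SampleRole.QC_LLOQ, SampleRole.QC_LOW, SampleRole.QC_MID, SampleRole.QC_HIGH)


def extract_features(
    acqs: Sequence[Acquisition],
    layout: Sequence[SampleRecord],
    config: PipelineConfig,
) -> pd.DataFrame:
    """Per-spot MobA areas, MassI intensities and IS-normalized responses."""
    by_id = {r.sample_id: r for r in layout}
    rows = []
    for acq in acqs:
        sid = acq.metadata.get("sample", {}).get("sample_id")
        rec = by_id[sid]
        a_area = moba(acq, config.analyte_window)
        i_area = moba(acq, config.is_window)
        resp = compute_response(a_area, i_area, sample_id=sid)
        rows.append(
            {
                "sample_id": sid,
                "role": rec.role.value,
                "level": rec.level,
                "nominal_conc_ng_per_mL": rec.nominal_conc,
                "batch_id": rec.batch_id,
                "replicate_id": rec.replicate_id,
                "freeze_thaw_cycles": rec.freeze_thaw_cycles,
                "analyte_moba": a_area,
                "is_moba": i_area,
                "analyte_massi": massi(acq, config.analyte_window),
                "is_massi": massi(acq, config.is_window),
                "response": resp.y,
                "response_valid": resp.valid,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class CampaignResult:
    report: "object"  # ValidationReport
    features: pd.DataFrame
    fits: dict[str, CalibrationResult]
    back_calc: pd.DataFrame
    config: PipelineConfig
    seed: int
    layouts: dict[str, list[SampleRecord]] = field(default_factory=dict)

    def write_artifacts(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {}
        for name, layout in self.layouts.items():
            p = outdir / f"layout_{name}.csv"
            layout_to_dataframe(layout).to_csv(p, index=False)
            paths[f"layout_{name}"] = p
        p = outdir / "features.csv"
        self.features.to_csv(p, index=False)
        paths["features"] = p
        p = outdir / "calibration_fits.json"
        p.write_text(
            json.dumps({b: f.to_dict() for b, f in sorted(self.fits.items())},
                       indent=1, sort_keys=True)
        )
        paths["fits"] = p
        p = outdir / "back_calculated.csv"
        self.back_calc.to_csv(p, index=False)
        paths["back_calc"] = p
        p = outdir / "report.json"
        p.write_text(self.report.to_json())
        paths["report"] = p
        p = outdir / "report.md"
        p.write_text(self.report.to_markdown())
        paths["report_md"] = p
        p = outdir / "run.log"
        p.write_text(
            f"mobiquant {__version__}\nseed {self.seed}\nconfig_hash {self.config.config_hash()}\n"
        )
        paths["log"] = p
        return paths


def _limits(config: PipelineConfig) -> AcceptanceLimits:
    v = config.validation
    return AcceptanceLimits(
        cv_limit_pct=v.cv_limit_pct,
        bias_limit_pct=v.bias_limit_pct,
        lloq_cv_limit_pct=v.lloq_cv_limit_pct,
        lloq_bias_limit_pct=v.lloq_bias_limit_pct,
        cv_strict=v.cv_strict,
        bias_strict=v.bias_strict,
        blank_analyte_limit_fraction=v.blank_analyte_limit_fraction,
        blank_is_limit_fraction=v.blank_is_limit_fraction,
    )


def _fit_batch(feat: pd.DataFrame, batch_id: str, config: PipelineConfig) -> CalibrationResult:
    cal = feat[(feat.batch_id == batch_id) & (feat.role == SampleRole.CAL.value)]
    model = CalibrationModel(
        cal["nominal_conc_ng_per_mL"].to_numpy(),
        cal["response"].to_numpy(),
        weighting=config.calibration.weighting,
        use_level_means=config.calibration.use_level_means,
    )
    return model.fit()


def _pa_row(pa, passed: bool) -> dict:
    return {
        "level": pa.level, "n": pa.n, "mean_measured": pa.mean_measured,
        "cv_pct": pa.cv_pct, "bias_pct": pa.bias_pct, "scope": pa.scope.value,
        "batch_id": pa.batch_id, "pass": passed,
    }


def run_campaign(config: PipelineConfig, seed: int | None = None) -> CampaignResult:
    """Run the full synthetic validation campaign and build the report."""
    seed = config.seed if seed is None else int(seed)
    instrument, signal = config.instrument, config.signal
    limits = _limits(config)
    n_batches = config.n_batches

    layouts: dict[str, list[SampleRecord]] = {}
    acqs: dict[str, list[Acquisition]] = {}

    for b in range(1, n_batches + 1):
        batch_id = f"B{b}"
        layout = build_batch_layout("validation", batch_id=batch_id)
        if b == 3:
            layout = layout + freeze_thaw_records(batch_id)
        if b == 4:
            layout = layout + build_batch_layout("carryover", batch_id=batch_id)
        layouts[batch_id] = layout
        acqs[batch_id] = simulate_batch(layout, instrument, signal, [seed, b])

    layouts["SPEC"] = [
        SampleRecord(sample_id=f"SPEC-BV-{k}", role=SampleRole.BV, level="BV",
                     batch_id="SPEC", replicate_id=k)
        for k in range(1, config.validation.min_blank_sources + 1)
    ]
    acqs["SPEC"] = simulate_batch(layouts["SPEC"], instrument, signal, [seed, 91])
    layouts["REC"] = build_batch_layout("recovery", batch_id="REC")
    acqs["REC"] = simulate_batch(layouts["REC"], instrument, signal, [seed, 92])
    layouts["MAT"] = build_batch_layout("matrix_effect", batch_id="MAT")
    acqs["MAT"] = simulate_batch(layouts["MAT"], instrument, signal, [seed, 93])

    all_layout = [r for lay in layouts.values() for r in lay]
    all_acqs = [a for group in acqs.values() for a in group]
    feat = extract_features(all_acqs, all_layout, config)

    # Per-batch calibration; a failed fit marks the batch rejected but the
    # campaign continues on the remaining batches.
    fits: dict[str, CalibrationResult] = {}
    cal_rows = []
    for b in range(1, n_batches + 1):
        batch_id = f"B{b}"
        try:
            fit = _fit_batch(feat, batch_id, config)
        except ValueError as exc:
            cal_rows.append({"batch_id": batch_id, "pass": False, "error": str(exc)})
            continue
        fits[batch_id] = fit
        acc = fit.evaluate(
            lloq_conc=QC_LEVELS_NG_PER_ML["LLOQ"],
            bias_limit_pct=config.calibration.bias_limit_pct,
            lloq_bias_limit_pct=config.calibration.lloq_bias_limit_pct,
            min_fraction=config.calibration.min_fraction,
            min_levels=config.calibration.min_levels,
            r2_threshold=config.calibration.r2_threshold,
        )
        cal_rows.append(
            {
                "batch_id": batch_id, "pass": acc.verdict, "r2": acc.r2, "r2_ok": acc.r2_ok,
                "fraction_accepted": acc.fraction_accepted,
                "accepted_levels": acc.accepted_levels, "n_levels": acc.n_levels,
                "slope": fit.slope, "intercept": fit.intercept,
            }
        )
    calibration_section = {
        "pass": bool(cal_rows) and all(r["pass"] for r in cal_rows),
        "range_ng_per_mL": [min(QC_LEVELS_NG_PER_ML.values()), 1000.0],
        "batches": cal_rows,
    }

    # Back-calculate QC concentrations with each batch's own curve.
    bc_rows = []
    qc_role_values = {r.value for r in _QC_ROLES}
    for batch_id, fit in fits.items():
        sub = feat[(feat.batch_id == batch_id) & feat.role.isin(qc_role_values)]
        for row in sub.itertuples(index=False):
            measured = fit.back_calculate(row.response)
            bc_rows.append(
                {
                    "sample_id": row.sample_id, "batch_id": batch_id, "role": row.role,
                    "level": row.level, "nominal_conc_ng_per_mL": row.nominal_conc_ng_per_mL,
                    "freeze_thaw_cycles": row.freeze_thaw_cycles,
                    "measured_conc_ng_per_mL": measured,
                    "below_zero": bool(measured < 0),
                }
            )
    back_calc = pd.DataFrame(bc_rows)

    pa_batches = [f"B{b}" for b in range(1, min(3, n_batches) + 1) if f"B{b}" in fits]

    def _pa_block(level_name: str, is_lloq: bool):
        nominal = QC_LEVELS_NG_PER_ML[level_name]
        rows, pooled = [], []
        for batch_id in pa_batches:
            vals = back_calc[
                (back_calc.batch_id == batch_id) & (back_calc.level == level_name)
            ]["measured_conc_ng_per_mL"].to_numpy()
            if len(vals) < 2:
                continue
            pa = precision_accuracy(vals, nominal, Scope.WITHIN_BATCH, batch_id=batch_id)
            rows.append(_pa_row(pa, check_acceptance(pa, is_lloq, limits)))
            pooled.extend(vals.tolist())
        b2b = precision_accuracy(pooled, nominal, Scope.BATCH_TO_BATCH)
        rows.append(_pa_row(b2b, check_acceptance(b2b, is_lloq, limits)))
        return rows

    sensitivity_rows = _pa_block("LLOQ", is_lloq=True)
    sensitivity_section = {
        "pass": all(r["pass"] for r in sensitivity_rows),
        "lloq_ng_per_mL": QC_LEVELS_NG_PER_ML["LLOQ"],
        "results": sensitivity_rows,
    }
    qc_rows = []
    for level_name in RECOVERY_QC_LEVELS:
        qc_rows.extend(_pa_block(level_name, is_lloq=False))
    qc_section = {"pass": all(r["pass"] for r in qc_rows), "results": qc_rows}

    # Freeze/thaw stability: the flagged quadruplicates of batch 3.
    freeze_thaw_section = None
    ft = back_calc[back_calc.freeze_thaw_cycles > 0] if len(back_calc) else back_calc
    if len(back_calc) and len(ft):
        ft_rows = []
        for level_name in sorted(ft.level.unique(), key=lambda n: QC_LEVELS_NG_PER_ML[n]):
            vals = ft[ft.level == level_name]["measured_conc_ng_per_mL"].to_numpy()
            pa = precision_accuracy(vals, QC_LEVELS_NG_PER_ML[level_name], Scope.WITHIN_BATCH,
                                    batch_id="B3")
            ft_rows.append(_pa_row(pa, check_acceptance(pa, False, limits)))
        freeze_thaw_section = {
            "pass": all(r["pass"] for r in ft_rows), "cycles": 3, "results": ft_rows,
        }

    # Reference signals for the blank checks: lowest LLOQ analyte area and
    # mean IS area over calibrators and QCs of the precision batches.
    ref = feat[feat.batch_id.isin(pa_batches)]
    lloq_signals = ref[ref.role == SampleRole.QC_LLOQ.value]["analyte_moba"]
    lowest_lloq = float(lloq_signals.min()) if len(lloq_signals) else float("nan")
    is_ref = ref[ref.role.isin(qc_role_values | {SampleRole.CAL.value})]["is_moba"]
    mean_is = float(is_ref.mean()) if len(is_ref) else float("nan")

    spec_feat = feat[feat.batch_id == "SPEC"]
    specificity_section = specificity_check(
        spec_feat["analyte_moba"].tolist(),
        spec_feat["is_moba"].tolist(),
        lowest_lloq,
        mean_is,
        limits=limits,
        min_sources=config.validation.min_blank_sources,
    )

    co_feat = feat[feat.role == SampleRole.CARRYOVER_BLANK.value]
    carryover_section = None
    if len(co_feat):
        co_batch = co_feat.batch_id.iloc[0]
        co_lloq = feat[
            (feat.batch_id == co_batch) & (feat.role == SampleRole.QC_LLOQ.value)
        ]["analyte_moba"]
        co_is = feat[
            (feat.batch_id == co_batch) & feat.role.isin(qc_role_values | {SampleRole.CAL.value})
        ]["is_moba"]
        carryover_section = carryover_check(
            co_feat["analyte_moba"].tolist(),
            co_feat["is_moba"].tolist(),
            float(co_lloq.min()),
            float(co_is.mean()),
            positions=co_feat["level"].tolist(),
            limits=limits,
        )

    rec_feat = feat[feat.batch_id == "REC"]
    recovery_results = []
    for level_name in RECOVERY_QC_LEVELS:
        dil = rec_feat[
            (rec_feat.level == level_name) & (rec_feat.role == SampleRole.QC_DIL.value)
        ]["response"].to_numpy()
        rec_series = rec_feat[
            (rec_feat.level == level_name) & (rec_feat.role == SampleRole.QC_REC.value)
        ]["response"].to_numpy()
        recovery_results.append(recovery(dil, rec_series, QC_LEVELS_NG_PER_ML[level_name]))

    mat_feat = feat[feat.batch_id == "MAT"]
    matrix_results = []
    for level_name in RECOVERY_QC_LEVELS:
        mat_pairs = mat_feat[
            (mat_feat.level == level_name) & (mat_feat.role == SampleRole.QC_MAT.value)
        ][["analyte_moba", "is_moba"]].to_numpy()
        el_pairs = mat_feat[
            (mat_feat.level == level_name) & (mat_feat.role == SampleRole.QC_EL.value)
        ][["analyte_moba", "is_moba"]].to_numpy()
        matrix_results.append(
            matrix_factor(mat_pairs, el_pairs, QC_LEVELS_NG_PER_ML[level_name])
        )

    report = build_validation_report(
        sensitivity=sensitivity_section,
        calibration=calibration_section,
        qc=qc_section,
        specificity=specificity_section,
        carryover=carryover_section,
        freeze_thaw=freeze_thaw_section,
        recovery_results=recovery_results,
        matrix_results=matrix_results,
    )
    return CampaignResult(
        report=report, features=feat, fits=fits, back_calc=back_calc,
        config=config, seed=seed, layouts=layouts,
    )
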