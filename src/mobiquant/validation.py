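"""FDA/EMA bioanalytical validation statistics and the summary report.

Definitions (per-level, on back-calculated concentrations):

    bias%  = 100 * (mean(measured) - nominal) / nominal
    CV%    = 100 * sd(measured) / mean(measured)          (sample sd, n-1)

Acceptance limits are 15% CV / +/-15% bias at ordinary QC levels and
20% / +/-20% at the LLOQ.  The CV limit is strict (a CV exactly at the
limit fails, matching the "<20%" phrasing of the guidelines), the bias
limit inclusive; both conventions are configurable.

Specificity and carry-over compare blank signals (MobA areas, the
validated extraction method) against the lowest LLOQ analyte signal
(limit 20%) and the mean IS signal (limit 5%).

The recovery and matrix-effect estimators implement the assay's
dilution-compensated designs:

* recovery% = 100 * mean(response of QC DIL) / mean(response of QC REC),
  where QC DIL is extracted then diluted 1:1 and QC REC represents 100%
  analyte recovery (analyte spiked post-extraction, IS co-extracted);
  IS normalization cancels the MALDI spot-to-spot variability.
* matrix factor MF% = 100 * mean(area in QC MAT) / mean(area in QC EL)
  per compound; the IS-normalized MF is MF(analyte)/MF(IS).  The MAT
  series starts from double plasma volume to compensate the
  post-extraction spike dilution.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "Scope",
    "AcceptanceLimits",
    "PrecisionAccuracy",
    "SpecificityResult",
    "CarryoverResult",
    "RecoveryResult",
    "MatrixFactorResult",
    "ValidationReport",
    "precision_accuracy",
    "check_acceptance",
    "specificity_check",
    "carryover_check",
    "recovery",
    "matrix_factor",
    "mean_normalized_matrix_factor",
    "build_validation_report",
]


class Scope(str, enum.Enum):
    WITHIN_BATCH = "within_batch"
    BATCH_TO_BATCH = "batch_to_batch"


@dataclass
class AcceptanceLimits:
    """Guideline limits; defaults are the regulatory values."""

    cv_limit_pct: float = 15.0
    bias_limit_pct: float = 15.0
    lloq_cv_limit_pct: float = 20.0
    lloq_bias_limit_pct: float = 20.0
    cv_strict: bool = True  # pass iff CV < limit
    bias_strict: bool = False  # pass iff |bias| <= limit
    blank_analyte_limit_fraction: float = 0.20  # of the lowest LLOQ analyte signal
    blank_is_limit_fraction: float = 0.05  # of the mean IS signal


@dataclass
class PrecisionAccuracy:
    level: float
    n: int
    mean_measured: float
    cv_pct: float
    bias_pct: float
    scope: Scope = Scope.WITHIN_BATCH
    batch_id: str | None = None


def precision_accuracy(
    measured: Sequence[float],
    nominal: float,
    scope: Scope | str = Scope.WITHIN_BATCH,
    batch_id: str | None = None,
) -> PrecisionAccuracy:
    """Precision (%CV) and accuracy (%bias) of replicate measured concentrations.

    Batch-to-batch statistics pool all replicates of all batches at the
    level (grand mean / grand sd), matching the single pooled values of
    the validation summary table.
    """
    arr = np.asarray(measured, dtype=float)
    if arr.size < 2:
        raise ValueError("precision requires n >= 2 replicates")
    if nominal <= 0:
        raise ValueError("nominal concentration must be > 0")
    mean = float(arr.mean())
    sd = float(arr.std(ddof=1))
    cv = 100.0 * sd / mean if mean != 0 else float("inf")
    bias = 100.0 * (mean - nominal) / nominal
    return PrecisionAccuracy(
        level=float(nominal), n=int(arr.size), mean_measured=mean,
        cv_pct=float(cv), bias_pct=float(bias), scope=Scope(scope), batch_id=batch_id,
    )


def check_acceptance(
    pa: PrecisionAccuracy,
    is_lloq: bool = False,
    limits: AcceptanceLimits | None = None,
) -> bool:
    """True iff both precision and accuracy are within the guideline limits."""
    limits = limits or AcceptanceLimits()
    cv_limit = limits.lloq_cv_limit_pct if is_lloq else limits.cv_limit_pct
    bias_limit = limits.lloq_bias_limit_pct if is_lloq else limits.bias_limit_pct
    cv_ok = pa.cv_pct < cv_limit if limits.cv_strict else pa.cv_pct <= cv_limit
    bias_ok = (
        abs(pa.bias_pct) < bias_limit if limits.bias_strict else abs(pa.bias_pct) <= bias_limit
    )
    return bool(cv_ok and bias_ok)


@dataclass
class SpecificityResult:
    n_sources: int
    analyte_ratios_pct: list[float]
    is_ratios_pct: list[float]
    max_analyte_ratio_pct: float
    max_is_ratio_pct: float
    verdict: bool
    warning: str | None = None


def _blank_ratio_check(
    analyte_signals: Sequence[float],
    is_signals: Sequence[float],
    lloq_analyte_signal: float,
    mean_is_signal: float,
    limits: AcceptanceLimits,
):
    if lloq_analyte_signal <= 0 or mean_is_signal <= 0:
        raise ValueError("reference signals must be > 0")
    a_ratios = [100.0 * s / lloq_analyte_signal for s in analyte_signals]
    i_ratios = [100.0 * s / mean_is_signal for s in is_signals]
    a_lim = 100.0 * limits.blank_analyte_limit_fraction
    i_lim = 100.0 * limits.blank_is_limit_fraction
    verdict = all(r < a_lim for r in a_ratios) and all(r < i_lim for r in i_ratios)
    return a_ratios, i_ratios, verdict


def specificity_check(
    blank_analyte_signals: Sequence[float],
    blank_is_signals: Sequence[float],
    lloq_analyte_signal: float,
    mean_is_signal: float,
    limits: AcceptanceLimits | None = None,
    min_sources: int = 6,
) -> SpecificityResult:
    """Interference check on blank plasma from independent sources.

    Per source, the analyte-window signal must stay below 20% of the
    lowest LLOQ analyte signal and the IS-window signal below 5% of the
    mean IS signal.  Fewer than ``min_sources`` sources yields a warning,
    not an error; the verdict is still computed.
    """
    limits = limits or AcceptanceLimits()
    if len(blank_analyte_signals) != len(blank_is_signals):
        raise ValueError("per-source signal lists must have equal length")
    a_ratios, i_ratios, verdict = _blank_ratio_check(
        blank_analyte_signals, blank_is_signals, lloq_analyte_signal, mean_is_signal, limits
    )
    warning = None
    if len(blank_analyte_signals) < min_sources:
        warning = (
            f"only {len(blank_analyte_signals)} blank sources; guidelines ask for {min_sources}"
        )
    return SpecificityResult(
        n_sources=len(blank_analyte_signals),
        analyte_ratios_pct=[float(r) for r in a_ratios],
        is_ratios_pct=[float(r) for r in i_ratios],
        max_analyte_ratio_pct=float(max(a_ratios, default=0.0)),
        max_is_ratio_pct=float(max(i_ratios, default=0.0)),
        verdict=verdict,
        warning=warning,
    )


@dataclass
class CarryoverResult:
    positions: list[str]
    analyte_ratios_pct: list[float]
    is_ratios_pct: list[float]
    mean_analyte_ratio_pct: float
    mean_is_ratio_pct: float
    verdict: bool


def carryover_check(
    blank_analyte_signals: Sequence[float],
    blank_is_signals: Sequence[float],
    lloq_analyte_signal: float,
    mean_is_signal: float,
    positions: Sequence[str] | None = None,
    limits: AcceptanceLimits | None = None,
) -> CarryoverResult:
    """Residual-signal check on blanks measured on former top-standard positions.

    Same thresholds as specificity (20% of the lowest LLOQ analyte signal,
    5% of the mean IS signal), applied to the mean over positions.
    """
    limits = limits or AcceptanceLimits()
    a_ratios, i_ratios, _ = _blank_ratio_check(
        blank_analyte_signals, blank_is_signals, lloq_analyte_signal, mean_is_signal, limits
    )
    mean_a = float(np.mean(a_ratios)) if a_ratios else 0.0
    mean_i = float(np.mean(i_ratios)) if i_ratios else 0.0
    verdict = bool(
        mean_a < 100.0 * limits.blank_analyte_limit_fraction
        and mean_i < 100.0 * limits.blank_is_limit_fraction
    )
    return CarryoverResult(
        positions=list(positions or [f"pos{i+1}" for i in range(len(a_ratios))]),
        analyte_ratios_pct=[float(r) for r in a_ratios],
        is_ratios_pct=[float(r) for r in i_ratios],
        mean_analyte_ratio_pct=mean_a,
        mean_is_ratio_pct=mean_i,
        verdict=verdict,
    )


@dataclass
class RecoveryResult:
    level: float
    recovery_pct: float
    cv_pct: float
    n: int


def recovery(
    qc_dil_responses: Sequence[float],
    qc_rec_responses: Sequence[float],
    level: float,
) -> RecoveryResult:
    """Extraction recovery from the paired QC DIL / QC REC series.

    recovery% = 100 * mean(IS-normalized QC DIL) / mean(IS-normalized
    QC REC).  Both series are prepared at matched final dilution, so the
    ratio isolates the extraction loss.  The CV is computed over
    replicate-paired DIL/REC ratios when the series have equal length,
    otherwise propagated from the two series' CVs.
    """
    dil = np.asarray(qc_dil_responses, dtype=float)
    rec = np.asarray(qc_rec_responses, dtype=float)
    if dil.size == 0 or rec.size == 0:
        raise ValueError("both QC DIL and QC REC series must be non-empty")
    if rec.mean() == 0:
        raise ValueError("QC REC mean response is zero")
    rec_pct = 100.0 * dil.mean() / rec.mean()
    if dil.size == rec.size and dil.size >= 2:
        ratios = dil / rec
        cv = 100.0 * ratios.std(ddof=1) / ratios.mean()
    elif dil.size >= 2 and rec.size >= 2:
        cv_d = dil.std(ddof=1) / dil.mean()
        cv_r = rec.std(ddof=1) / rec.mean()
        cv = 100.0 * float(np.hypot(cv_d, cv_r))
    else:
        cv = 0.0
    return RecoveryResult(level=float(level), recovery_pct=float(rec_pct),
                          cv_pct=float(cv), n=int(dil.size))


@dataclass
class MatrixFactorResult:
    level: float
    mf_analyte_pct: float
    mf_is_pct: float
    mf_normalized_pct: float
    cv_pct: float
    n: int


def matrix_factor(
    qc_mat_pairs: Sequence[tuple[float, float]],
    qc_el_pairs: Sequence[tuple[float, float]],
    level: float,
) -> MatrixFactorResult:
    """Per-compound and IS-normalized matrix factors from area pairs.

    ``qc_mat_pairs`` / ``qc_el_pairs`` are (analyte_area, is_area) pairs.
    MF_compound% = 100 * mean(area in MAT) / mean(area in EL); the
    IS-normalized MF is MF_analyte / MF_IS.  The CV is over per-replicate
    normalized ratios, response(MAT_i) / mean response(EL).
    """
    mat = np.asarray(qc_mat_pairs, dtype=float)
    el = np.asarray(qc_el_pairs, dtype=float)
    if mat.size == 0 or el.size == 0:
        raise ValueError("both QC MAT and QC EL series must be non-empty")
    if (el[:, 0].mean() == 0) or (el[:, 1].mean() == 0):
        raise ValueError("QC EL mean area is zero")
    mf_a = 100.0 * mat[:, 0].mean() / el[:, 0].mean()
    mf_i = 100.0 * mat[:, 1].mean() / el[:, 1].mean()
    mf_norm = 100.0 * mf_a / mf_i
    el_resp = el[:, 0] / el[:, 1]
    mat_resp = mat[:, 0] / mat[:, 1]
    ratios = mat_resp / el_resp.mean()
    cv = 100.0 * ratios.std(ddof=1) / ratios.mean() if len(ratios) >= 2 else 0.0
    return MatrixFactorResult(
        level=float(level), mf_analyte_pct=float(mf_a), mf_is_pct=float(mf_i),
        mf_normalized_pct=float(mf_norm), cv_pct=float(cv), n=int(len(mat)),
    )


def mean_normalized_matrix_factor(results: Sequence[MatrixFactorResult]) -> float:
    """Mean of the per-level IS-normalized matrix factors (%)."""
    if not results:
        raise ValueError("no matrix-factor results")
    return float(np.mean([r.mf_normalized_pct for r in results]))


def _pa_dict(pa: PrecisionAccuracy, passed: bool) -> dict:
    return {
        "level": pa.level, "n": pa.n, "mean_measured": pa.mean_measured,
        "cv_pct": pa.cv_pct, "bias_pct": pa.bias_pct, "scope": pa.scope.value,
        "batch_id": pa.batch_id, "pass": passed,
    }


@dataclass
class ValidationReport:
    """Structured validation summary mirroring the assay's Table-2 layout.

    ``sections`` maps section name (sensitivity, calibration, qc,
    specificity, carryover, freeze_thaw, recovery, matrix_effect) to a
    serializable dict with at least a ``pass`` key, or to None when the
    section was not assessed.  The overall verdict is ``validated`` when
    every assessed section passes and none is missing, ``incomplete``
    when a section is missing, ``failed`` otherwise.
    """

    sections: dict = field(default_factory=dict)

    SECTION_ORDER = (
        "sensitivity", "calibration", "qc", "specificity", "carryover",
        "freeze_thaw", "recovery", "matrix_effect",
    )

    @property
    def overall_verdict(self) -> str:
        missing = [s for s in self.SECTION_ORDER if self.sections.get(s) is None]
        assessed = [self.sections[s] for s in self.SECTION_ORDER if self.sections.get(s) is not None]
        if any(not sec.get("pass", False) for sec in assessed):
            return "failed"
        if missing:
            return "incomplete"
        return "validated"

    def to_dict(self) -> dict:
        return {
            "sections": {s: self.sections.get(s) for s in self.SECTION_ORDER},
            "overall_verdict": self.overall_verdict,
        }

    def to_json(self, indent: int | None = 1) -> str:
        return json.dumps(self.to_dict(), indent=indent, sort_keys=True)

    @classmethod
    def from_dict(cls, payload: dict) -> "ValidationReport":
        sections = {
            k: v for k, v in payload.get("sections", {}).items()
        }
        return cls(sections=sections)

    @classmethod
    def from_json(cls, text: str) -> "ValidationReport":
        return cls.from_dict(json.loads(text))

    def to_markdown(self) -> str:
        lines = ["# Validation summary", ""]
        for name in self.SECTION_ORDER:
            sec = self.sections.get(name)
            lines.append(f"## {name.replace('_', ' ').title()}")
            if sec is None:
                lines.append("not assessed")
            else:
                lines.append("**PASS**" if sec.get("pass") else "**FAIL**")
                for key, value in sec.items():
                    if key == "pass":
                        continue
                    lines.append(f"- {key}: {json.dumps(value) if isinstance(value, (dict, list)) else value}")
            lines.append("")
        lines.append(f"**Overall: {self.overall_verdict}**")
        return "\n".join(lines)


def build_validation_report(
    sensitivity: dict | None = None,
    calibration: dict | None = None,
    qc: dict | None = None,
    specificity: SpecificityResult | dict | None = None,
    carryover: CarryoverResult | dict | None = None,
    freeze_thaw: dict | None = None,
    recovery_results: Sequence[RecoveryResult] | dict | None = None,
    matrix_results: Sequence[MatrixFactorResult] | dict | None = None,
) -> ValidationReport:
    """Assemble component results into a serializable validation report."""

    def spec_dict(res):
        if res is None or isinstance(res, dict):
            return res
        return {
            "pass": res.verdict, "n_sources": res.n_sources,
            "max_analyte_ratio_pct": res.max_analyte_ratio_pct,
            "max_is_ratio_pct": res.max_is_ratio_pct,
            "analyte_ratios_pct": res.analyte_ratios_pct,
            "is_ratios_pct": res.is_ratios_pct,
            "warning": res.warning,
        }

    def carry_dict(res):
        if res is None or isinstance(res, dict):
            return res
        return {
            "pass": res.verdict, "positions": res.positions,
            "mean_analyte_ratio_pct": res.mean_analyte_ratio_pct,
            "mean_is_ratio_pct": res.mean_is_ratio_pct,
            "analyte_ratios_pct": res.analyte_ratios_pct,
            "is_ratios_pct": res.is_ratios_pct,
        }

    def recovery_dict(res):
        if res is None or isinstance(res, dict):
            return res
        rows = [
            {"level": r.level, "recovery_pct": r.recovery_pct, "cv_pct": r.cv_pct, "n": r.n}
            for r in res
        ]
        overall = float(np.mean([r.recovery_pct for r in res])) if rows else float("nan")
        overall_cv = float(np.mean([r.cv_pct for r in res])) if rows else float("nan")
        return {"pass": bool(rows) and all(r.recovery_pct > 0 for r in res),
                "per_level": rows, "mean_recovery_pct": overall, "mean_cv_pct": overall_cv}

    def matrix_dict(res):
        if res is None or isinstance(res, dict):
            return res
        rows = [
            {
                "level": r.level, "mf_analyte_pct": r.mf_analyte_pct,
                "mf_is_pct": r.mf_is_pct, "mf_normalized_pct": r.mf_normalized_pct,
                "cv_pct": r.cv_pct, "n": r.n,
            }
            for r in res
        ]
        mean_mf = mean_normalized_matrix_factor(list(res)) if rows else float("nan")
        return {"pass": bool(rows) and all(r.mf_normalized_pct > 0 for r in res),
                "per_level": rows, "mean_normalized_mf_pct": mean_mf}

    return ValidationReport(
        sections={
            "sensitivity": sensitivity,
            "calibration": calibration,
            "qc": qc,
            "specificity": spec_dict(specificity),
            "carryover": carry_dict(carryover),
            "freeze_thaw": freeze_thaw,
            "recovery": recovery_dict(recovery_results),
            "matrix_effect": matrix_dict(matrix_results),
        }
    )
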