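"""Pipeline configuration: one validated object, single source of truth.

Every threshold carries the guideline/assay default; unknown keys are
rejected by name on load.  Units are fixed (concentrations ng/mL, drift
times ms) — no unit inference anywhere.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field

from .mobilogram import ANALYTE_WINDOW, IS_WINDOW, ExtractionWindow
from .simulate import InstrumentModel, SignalModel

__all__ = ["CalibrationConfig", "ValidationConfig", "CrossValConfig", "PipelineConfig"]


class CalibrationConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    weighting: str = "1/x^2"
    use_level_means: bool = False
    r2_threshold: float = 0.988
    bias_limit_pct: float = 15.0
    lloq_bias_limit_pct: float = 20.0
    min_fraction: float = 0.75
    min_levels: int = 6


class ValidationConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    cv_limit_pct: float = 15.0
    bias_limit_pct: float = 15.0
    lloq_cv_limit_pct: float = 20.0
    lloq_bias_limit_pct: float = 20.0
    cv_strict: bool = True
    bias_strict: bool = False
    blank_analyte_limit_fraction: float = 0.20
    blank_is_limit_fraction: float = 0.05
    min_blank_sources: int = 6


class CrossValConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    limit_pct: float = 20.0
    min_fraction: float = 0.67
    min_n: int = 20


class PipelineConfig(BaseModel):
    """Full campaign configuration (instrument, signal, windows, thresholds)."""

    model_config = ConfigDict(extra="forbid")

    instrument: InstrumentModel = Field(default_factory=InstrumentModel)
    signal: SignalModel = Field(default_factory=SignalModel)
    analyte_window: ExtractionWindow = Field(default_factory=lambda: ANALYTE_WINDOW.model_copy())
    is_window: ExtractionWindow = Field(default_factory=lambda: IS_WINDOW.model_copy())
    calibration: CalibrationConfig = Field(default_factory=CalibrationConfig)
    validation: ValidationConfig = Field(default_factory=ValidationConfig)
    crossval: CrossValConfig = Field(default_factory=CrossValConfig)
    n_batches: int = Field(4, ge=1)
    seed: int = 0

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        text = path.read_text()
        payload = json.loads(text) if path.suffix.lower() == ".json" else yaml.safe_load(text)
        return cls.model_validate(payload or {})

    def to_file(self, path: str | Path) -> None:
        path = Path(path)
        payload = json.loads(self.model_dump_json())
        if path.suffix.lower() == ".json":
            path.write_text(json.dumps(payload, indent=1))
        else:
            path.write_text(yaml.safe_dump(payload, sort_keys=False))

    def config_hash(self) -> str:
        return hashlib.sha256(self.model_dump_json().encode()).hexdigest()[:16]
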