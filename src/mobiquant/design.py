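"""Sample-preparation arithmetic and batch layouts.

The assay quantifies osimertinib in human plasma.  Calibration standards
(CAL) and quality controls (QC) are prepared by mixing 100 µL of plasma
with 50 µL of an analyte reference solution and 50 µL of the internal
standard (IS, [13C,2H3]-osimertinib) solution, then extracting with
tert-butyl methyl ether and spotting 1 µL of the organic layer on a MALDI
target.  Because the 50 µL spike refers the analyte mass back to the
100 µL of plasma, the *virtual concentration in plasma* is half the
solution concentration.

Concentrations are stored throughout as virtual concentrations in plasma
(ng/mL); solution concentrations are derived on demand and never stored,
which removes a whole class of double-conversion bugs.
"""

from __future__ import annotations

import enum
import json
from pathlib import Path
from typing import Sequence

import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator

__all__ = [
    "SampleRole",
    "SpikePlan",
    "SampleRecord",
    "CAL_LEVELS_NG_PER_ML",
    "QC_LEVELS_NG_PER_ML",
    "IS_SOLUTION_NG_PER_ML",
    "RECOVERY_QC_LEVELS",
    "virtual_plasma_concentration",
    "solution_concentration",
    "build_batch_layout",
    "freeze_thaw_records",
    "layout_to_dataframe",
    "layout_from_dataframe",
    "write_layout",
    "read_layout",
    "LAYOUT_COLUMNS",
]

#: Non-zero calibration levels, virtual ng/mL in plasma (CAL5 ... CAL1000).
CAL_LEVELS_NG_PER_ML: tuple[float, ...] = (5.0, 10.0, 20.0, 50.0, 100.0, 200.0, 500.0, 1000.0)

#: QC levels, virtual ng/mL in plasma.
QC_LEVELS_NG_PER_ML: dict[str, float] = {"LLOQ": 5.0, "LQC": 15.0, "MQC": 400.0, "HQC": 800.0}

#: IS working-solution concentration (ng/mL); spiked at a fixed volume into every sample.
IS_SOLUTION_NG_PER_ML: float = 400.0

#: Levels used in the recovery and matrix-effect designs.
RECOVERY_QC_LEVELS: tuple[str, ...] = ("LQC", "MQC", "HQC")


class SampleRole(str, enum.Enum):
    """Role of a spot within a batch."""

    BV = "BV"  # blind value: unspiked control plasma
    CAL0 = "CAL0"  # control plasma spiked with IS only
    CAL = "CAL"  # non-zero calibration standard
    QC_LLOQ = "QC_LLOQ"
    QC_LOW = "QC_LOW"
    QC_MID = "QC_MID"
    QC_HIGH = "QC_HIGH"
    QC_DIL = "QC_DIL"  # diluted QC (recovery design, extracted then 1:1 diluted)
    QC_REC = "QC_REC"  # 100%-recovery reference (analyte spiked post-extraction)
    QC_MAT = "QC_MAT"  # post-extraction matrix spike (matrix-effect design)
    QC_EL = "QC_EL"  # neat-eluent spike (matrix-effect design)
    CARRYOVER_BLANK = "CARRYOVER_BLANK"
    CLINICAL = "CLINICAL"


#: Roles whose nominal in-plasma concentration is exactly zero.  QC_EL
#: contains analyte, but in neat eluent, not plasma; its spike level is
#: carried by ``level``.
ZERO_CONC_ROLES = frozenset(
    {SampleRole.BV, SampleRole.CAL0, SampleRole.QC_EL, SampleRole.CARRYOVER_BLANK}
)

QC_ROLE_BY_LEVEL = {
    "LLOQ": SampleRole.QC_LLOQ,
    "LQC": SampleRole.QC_LOW,
    "MQC": SampleRole.QC_MID,
    "HQC": SampleRole.QC_HIGH,
}


class SpikePlan(BaseModel):
    """Volumetric plan of the spike-and-extract preparation (§ sample prep).

    All volumes in µL.  The defaults reproduce the assay's standard
    preparation: 100 µL plasma + 50 µL reference solution + 50 µL IS
    solution, extracted with 200 µL of solvent, no post-extraction
    dilution.
    """

    model_config = ConfigDict(extra="forbid")

    plasma_volume_ul: float = Field(100.0, gt=0)
    analyte_spike_volume_ul: float = Field(50.0, gt=0)
    is_spike_volume_ul: float = Field(50.0, gt=0)
    extraction_solvent_volume_ul: float = Field(200.0, gt=0)
    post_extraction_dilution_factor: float = Field(1.0, ge=1.0)


def virtual_plasma_concentration(plan: SpikePlan, solution_conc: float) -> float:
    """Virtual in-plasma concentration (ng/mL) from a spike-solution concentration.

    The spiked analyte mass ``solution_conc * spike_volume`` is referred to
    the plasma volume, the convention the assay's concentration table uses
    (2000 ng/mL solution -> 1000 ng/mL virtual with a 50 µL spike into
    100 µL plasma).  The IS spike volume does not enter the denominator.
    """
    if not isinstance(plan, SpikePlan):
        raise TypeError("plan must be a SpikePlan")
    if solution_conc < 0:
        raise ValueError("solution_conc must be >= 0")
    return solution_conc * plan.analyte_spike_volume_ul / plan.plasma_volume_ul


def solution_concentration(plan: SpikePlan, virtual_conc: float) -> float:
    """Inverse of :func:`virtual_plasma_concentration` (derived, never stored)."""
    if virtual_conc < 0:
        raise ValueError("virtual_conc must be >= 0")
    return virtual_conc * plan.plasma_volume_ul / plan.analyte_spike_volume_ul


class SampleRecord(BaseModel):
    """One prepared spot: role, nominal concentration and condition flags.

    ``nominal_conc`` is the virtual concentration in plasma (ng/mL); it is
    exactly 0 for blanks (BV, CAL0, carry-over) and for neat-eluent spikes
    (QC_EL, whose analyte level is carried by ``level``), and unknown
    (None) for clinical samples.  ``true_conc`` is only meaningful for
    simulated clinical samples, where it carries the generator's ground
    truth.
    """

    model_config = ConfigDict(extra="forbid")

    sample_id: str
    role: SampleRole
    level: str | None = None
    nominal_conc: float | None = None
    batch_id: str = "B1"
    replicate_id: int = Field(1, ge=1)
    freeze_thaw_cycles: int = Field(0, ge=0)
    prespotted_matrix: bool = True
    true_conc: float | None = None

    @model_validator(mode="after")
    def _check_conc(self) -> "SampleRecord":
        if self.role in ZERO_CONC_ROLES:
            if self.nominal_conc is None:
                object.__setattr__(self, "nominal_conc", 0.0)
            elif self.nominal_conc != 0:
                raise ValueError(
                    f"{self.role.value} samples must have nominal_conc == 0, got {self.nominal_conc}"
                )
        elif self.role is SampleRole.CLINICAL:
            pass  # unknown nominal concentration is the point
        else:
            if self.nominal_conc is None or self.nominal_conc <= 0:
                raise ValueError(f"{self.role.value} samples require nominal_conc > 0")
        return self


def _cal_records(batch_id: str, levels: Sequence[float], replicates: int, prespotted: bool):
    records = []
    for rep in range(1, replicates + 1):
        records.append(
            SampleRecord(
                sample_id=f"{batch_id}-BV-{rep}", role=SampleRole.BV, level="BV",
                batch_id=batch_id, replicate_id=rep, prespotted_matrix=prespotted,
            )
        )
        records.append(
            SampleRecord(
                sample_id=f"{batch_id}-CAL0-{rep}", role=SampleRole.CAL0, level="CAL0",
                batch_id=batch_id, replicate_id=rep, prespotted_matrix=prespotted,
            )
        )
        for lvl in levels:
            name = f"CAL{lvl:g}"
            records.append(
                SampleRecord(
                    sample_id=f"{batch_id}-{name}-{rep}", role=SampleRole.CAL, level=name,
                    nominal_conc=float(lvl), batch_id=batch_id, replicate_id=rep,
                    prespotted_matrix=prespotted,
                )
            )
    return records


def freeze_thaw_records(batch_id: str, cycles: int = 3, replicates: int = 4, prespotted: bool = True):
    """Freeze/thaw stability QCs: ordinary LQC/MQC/HQC records flagged with the cycle count.

    They pool into the precision/accuracy statistics of their batch and are
    additionally reported as a stability row.
    """
    records = []
    for lvl_name in RECOVERY_QC_LEVELS:
        conc = QC_LEVELS_NG_PER_ML[lvl_name]
        for rep in range(1, replicates + 1):
            records.append(
                SampleRecord(
                    sample_id=f"{batch_id}-FT-{lvl_name}-{rep}",
                    role=QC_ROLE_BY_LEVEL[lvl_name], level=lvl_name,
                    nominal_conc=conc, batch_id=batch_id, replicate_id=rep,
                    freeze_thaw_cycles=cycles, prespotted_matrix=prespotted,
                )
            )
    return records


def build_batch_layout(
    design: str,
    levels: Sequence[float] | None = None,
    batch_id: str = "B1",
    prespotted: bool = True,
    n_clinical: int = 0,
) -> list[SampleRecord]:
    """Deterministic sample layout for one batch of a given design.

    Designs
    -------
    ``validation``
        4 technical replicates of BV, CAL0 and each non-zero CAL level,
        plus 8 replicates of the four QC levels (LLOQ, LQC, MQC, HQC).
        With the standard 8 CAL levels: 4*(2+8) + 8*4 = 72 records.
    ``analytical``
        2 replicates of BV/CAL0/CALs and of the three QC levels, plus
        technical duplicates of ``n_clinical`` clinical samples.
    ``recovery``
        4 replicates per level of the paired QC DIL / QC REC series.
    ``matrix_effect``
        4 replicates per level of the paired QC MAT / QC EL series.
    ``carryover``
        Two blanks on the former CAL500 and CAL1000 target positions.
    """
    if design == "validation":
        cal_levels = tuple(levels) if levels is not None else CAL_LEVELS_NG_PER_ML
        if not cal_levels:
            raise ValueError("validation design requires non-empty CAL levels")
        records = _cal_records(batch_id, cal_levels, replicates=4, prespotted=prespotted)
        for lvl_name, conc in QC_LEVELS_NG_PER_ML.items():
            for rep in range(1, 9):
                records.append(
                    SampleRecord(
                        sample_id=f"{batch_id}-QC-{lvl_name}-{rep}",
                        role=QC_ROLE_BY_LEVEL[lvl_name], level=lvl_name,
                        nominal_conc=conc, batch_id=batch_id, replicate_id=rep,
                        prespotted_matrix=prespotted,
                    )
                )
        return records

    if design == "analytical":
        cal_levels = tuple(levels) if levels is not None else CAL_LEVELS_NG_PER_ML
        records = _cal_records(batch_id, cal_levels, replicates=2, prespotted=prespotted)
        for lvl_name in RECOVERY_QC_LEVELS:
            conc = QC_LEVELS_NG_PER_ML[lvl_name]
            for rep in (1, 2):
                records.append(
                    SampleRecord(
                        sample_id=f"{batch_id}-QC-{lvl_name}-{rep}",
                        role=QC_ROLE_BY_LEVEL[lvl_name], level=lvl_name,
                        nominal_conc=conc, batch_id=batch_id, replicate_id=rep,
                        prespotted_matrix=prespotted,
                    )
                )
        for k in range(1, n_clinical + 1):
            for rep in (1, 2):
                records.append(
                    SampleRecord(
                        sample_id=f"{batch_id}-CLIN{k}-{rep}", role=SampleRole.CLINICAL,
                        level=f"CLIN{k}", batch_id=batch_id, replicate_id=rep,
                        prespotted_matrix=prespotted,
                    )
                )
        return records

    if design in ("recovery", "matrix_effect"):
        if levels is not None:
            level_items = [(f"L{lvl:g}", float(lvl)) for lvl in levels]
        else:
            level_items = [(n, QC_LEVELS_NG_PER_ML[n]) for n in RECOVERY_QC_LEVELS]
        if not level_items:
            raise ValueError(f"{design} design requires non-empty levels")
        pair = (
            (SampleRole.QC_DIL, SampleRole.QC_REC)
            if design == "recovery"
            else (SampleRole.QC_MAT, SampleRole.QC_EL)
        )
        records = []
        for lvl_name, conc in level_items:
            for role in pair:
                for rep in range(1, 5):
                    nominal = 0.0 if role is SampleRole.QC_EL else conc
                    records.append(
                        SampleRecord(
                            sample_id=f"{batch_id}-{role.value}-{lvl_name}-{rep}",
                            role=role, level=lvl_name, nominal_conc=nominal,
                            batch_id=batch_id, replicate_id=rep, prespotted_matrix=prespotted,
                        )
                    )
        return records

    if design == "carryover":
        return [
            SampleRecord(
                sample_id=f"{batch_id}-CO-postCAL500", role=SampleRole.CARRYOVER_BLANK,
                level="post-CAL500", batch_id=batch_id, replicate_id=1,
                prespotted_matrix=prespotted,
            ),
            SampleRecord(
                sample_id=f"{batch_id}-CO-postCAL1000", role=SampleRole.CARRYOVER_BLANK,
                level="post-CAL1000", batch_id=batch_id, replicate_id=2,
                prespotted_matrix=prespotted,
            ),
        ]

    raise ValueError(f"unknown batch design: {design!r}")


LAYOUT_COLUMNS = (
    "sample_id",
    "role",
    "level",
    "nominal_conc_ng_per_mL",
    "batch_id",
    "replicate_id",
    "freeze_thaw_cycles",
    "prespotted_matrix",
)


def layout_to_dataframe(records: Sequence[SampleRecord]) -> pd.DataFrame:
    rows = [
        {
            "sample_id": r.sample_id,
            "role": r.role.value,
            "level": r.level,
            "nominal_conc_ng_per_mL": r.nominal_conc,
            "batch_id": r.batch_id,
            "replicate_id": r.replicate_id,
            "freeze_thaw_cycles": r.freeze_thaw_cycles,
            "prespotted_matrix": r.prespotted_matrix,
        }
        for r in records
    ]
    return pd.DataFrame(rows, columns=list(LAYOUT_COLUMNS))


def layout_from_dataframe(df: pd.DataFrame) -> list[SampleRecord]:
    missing = set(LAYOUT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"layout table is missing columns: {sorted(missing)}")
    records = []
    for row in df.itertuples(index=False):
        conc = row.nominal_conc_ng_per_mL
        conc = None if conc is None or (isinstance(conc, float) and pd.isna(conc)) else float(conc)
        level = None if (row.level is None or (isinstance(row.level, float) and pd.isna(row.level))) else str(row.level)
        records.append(
            SampleRecord(
                sample_id=str(row.sample_id),
                role=SampleRole(row.role),
                level=level,
                nominal_conc=conc,
                batch_id=str(row.batch_id),
                replicate_id=int(row.replicate_id),
                freeze_thaw_cycles=int(row.freeze_thaw_cycles),
                prespotted_matrix=bool(row.prespotted_matrix),
            )
        )
    return records


def write_layout(records: Sequence[SampleRecord], path: str | Path) -> None:
    """Write a layout as CSV or JSON depending on the file suffix."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        payload = [json.loads(r.model_dump_json()) for r in records]
        path.write_text(json.dumps(payload, indent=1))
    else:
        layout_to_dataframe(records).to_csv(path, index=False)


def read_layout(path: str | Path) -> list[SampleRecord]:
    path = Path(path)
    if path.suffix.lower() == ".json":
        payload = json.loads(path.read_text())
        return [SampleRecord.model_validate(item) for item in payload]
    return layout_from_dataframe(pd.read_csv(path))
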