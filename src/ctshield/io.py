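"""File formats: room-specification JSON, workload and survey CSVs.

One unit system at every file boundary: angles as integer degrees,
distances in cm, doses in mSv, DLP in mGy·cm, workload in mAs.  The
room spec is schema-validated with unknown keys rejected (errors carry
the JSON path of the offending field).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Literal

import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, ValidationError, model_validator

from . import core, methods, shielding
from .survey import SurveyRecord

__all__ = [
    "RoomSpecError",
    "BarrierModel",
    "PointModel",
    "ConstraintModel",
    "JCParamsModel",
    "RoomSpec",
    "load_room",
    "read_workloads_csv",
    "read_survey_csv",
    "write_survey_csv",
]


class RoomSpecError(ValueError):
    """Raised for a malformed room-specification document."""


class _StrictModel(BaseModel):
    model_config = ConfigDict(extra="forbid")


class BarrierModel(_StrictModel):
    thickness_mm: float = 0.0
    model: Literal["hvl", "archer"] = "hvl"
    half_value_mm: float | None = None
    alpha: float | None = None
    beta: float | None = None
    gamma: float | None = None

    def to_spec(self) -> core.BarrierSpec:
        return core.BarrierSpec(
            thickness_mm=self.thickness_mm,
            model=self.model,
            half_value_mm=self.half_value_mm,
            alpha=self.alpha,
            beta=self.beta,
            gamma=self.gamma,
        )


class PointModel(_StrictModel):
    angle_deg: int
    distance_cm: float = Field(gt=0)
    occupancy: float = Field(default=1.0, gt=0, le=1)
    barrier: BarrierModel | None = None
    label: str | None = None

    @model_validator(mode="after")
    def _angle_admissible(self):
        if self.angle_deg not in core.ADMISSIBLE_ANGLES:
            raise ValueError(
                f"angle_deg must be one of {core.ADMISSIBLE_ANGLES}, "
                f"got {self.angle_deg}"
            )
        return self

    def to_point(self) -> core.EvaluationPoint:
        return core.EvaluationPoint(
            direction=core.DirectionLabel(self.angle_deg),
            distance_cm=self.distance_cm,
            occupancy_T=self.occupancy,
            barrier=self.barrier.to_spec() if self.barrier else None,
            label=self.label or f"{self.angle_deg}deg",
        )


class ConstraintModel(_StrictModel):
    limit_mSv: float = Field(default=1.3, gt=0)
    period: str = "3 months"

    def to_constraint(self) -> shielding.DoseConstraint:
        return shielding.DoseConstraint(self.limit_mSv, self.period)


class JCParamsModel(_StrictModel):
    x_per_mAs: float = Field(gt=0)
    scatter_fraction_a: float = Field(gt=0)
    field_F_cm2: float = Field(gt=0)
    beam_on_time_h: float = Field(default=0.0, ge=0)
    leakage_rate_XL: float = Field(default=1.0, gt=0)
    gantry_lead_equiv_mm: float = Field(default=2.5, ge=0)
    lead_half_value_mm: float = Field(default=0.25, gt=0)
    d1_m: float = Field(default=1.0, gt=0)
    d2_m: float = Field(default=1.0, gt=0)
    d3_m: float = Field(default=1.0, gt=0)
    d4_m: float = Field(default=1.0, gt=0)
    use_factor_U: float = Field(default=1.0, gt=0)

    def to_params(self) -> methods.JCParams:
        return methods.JCParams(**self.model_dump())


class RoomSpec(_StrictModel):
    """A CT room: evaluation points, constraint and method parameters."""

    scanner_id: str | None = None
    points: list[PointModel]
    constraint: ConstraintModel = ConstraintModel()
    jc: JCParamsModel | None = None
    weeks_per_period: float = Field(default=core.WEEKS_PER_THREE_MONTHS, gt=0)

    def evaluation_points(self) -> list[core.EvaluationPoint]:
        return [p.to_point() for p in self.points]


def load_room(path: str | Path) -> RoomSpec:
    """Parse and validate a room-spec JSON document."""
    try:
        payload = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise RoomSpecError(f"{path}: not valid JSON ({exc})") from exc
    try:
        return RoomSpec.model_validate(payload)
    except ValidationError as exc:
        details = "; ".join(
            f"{'.'.join(str(p) for p in err['loc']) or '<root>'}: {err['msg']}"
            for err in exc.errors()
        )
        raise RoomSpecError(f"{path}: invalid room spec ({details})") from exc


_WORKLOAD_REQUIRED = ("scanner_id", "dlp_head_mGycm", "dlp_body_mGycm")


def read_workloads_csv(path: str | Path) -> dict[str, core.WorkloadSummary]:
    """Read per-scanner workload summaries.

    Required columns: scanner_id, dlp_head_mGycm, dlp_body_mGycm.
    Optional: workload_head_mAs, workload_body_mAs, period_weeks.
    """
    df = pd.read_csv(path)
    missing = [c for c in _WORKLOAD_REQUIRED if c not in df.columns]
    if missing:
        raise RoomSpecError(f"{path}: workload CSV is missing columns {missing}")
    out: dict[str, core.WorkloadSummary] = {}
    for _, row in df.iterrows():
        def _opt(col: str) -> float | None:
            if col not in df.columns or pd.isna(row[col]):
                return None
            return float(row[col])

        out[str(row["scanner_id"])] = core.WorkloadSummary(
            scanner_id=str(row["scanner_id"]),
            dlp_head=float(row["dlp_head_mGycm"]),
            dlp_body=float(row["dlp_body_mGycm"]),
            workload_head_mAs=_opt("workload_head_mAs"),
            workload_body_mAs=_opt("workload_body_mAs"),
            period_weeks=_opt("period_weeks") or 1.0,
        )
    return out


_SURVEY_REQUIRED = ("scanner_id", "angle_deg", "net_dose_mSv", "distance_cm")


def read_survey_csv(path: str | Path) -> list[SurveyRecord]:
    """Read measured survey records (net doses at the measurement point)."""
    df = pd.read_csv(path)
    missing = [c for c in _SURVEY_REQUIRED if c not in df.columns]
    if missing:
        raise RoomSpecError(f"{path}: survey CSV is missing columns {missing}")
    records = []
    for _, row in df.iterrows():
        if "detected" in df.columns:
            records.append(
                SurveyRecord(
                    scanner_id=str(row["scanner_id"]),
                    direction=core.DirectionLabel(int(row["angle_deg"])),
                    net_dose_mSv=float(row["net_dose_mSv"]),
                    distance_cm=float(row["distance_cm"]),
                    detected=bool(row["detected"]),
                )
            )
        else:
            records.append(
                SurveyRecord.from_measurement(
                    str(row["scanner_id"]),
                    int(row["angle_deg"]),
                    float(row["net_dose_mSv"]),
                    float(row["distance_cm"]),
                )
            )
    return records


def write_survey_csv(records, path: str | Path) -> None:
    """Write survey records in the same dialect :func:`read_survey_csv` reads."""
    pd.DataFrame(
        {
            "scanner_id": r.scanner_id,
            "angle_deg": r.direction.angle_deg,
            "net_dose_mSv": r.net_dose_mSv,
            "distance_cm": r.distance_cm,
            "detected": r.detected,
        }
        for r in records
    ).to_csv(path, index=False)
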