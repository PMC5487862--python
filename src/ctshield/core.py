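"""Shared domain types, unit conventions and direction geometry.

Unit conventions used throughout the package: distances in cm, doses in
mSv, dose-length product (DLP) in mGy·cm, tube workload in mAs.  The
scatter engines work at a reference distance of 1 m (100 cm) from the
isocenter and scale with the inverse square of distance.

Eight evaluation directions are admitted, at 45° steps around the
isocenter.  Each direction belongs to a geometric class that determines
how much self-shielding (from the gantry or from the patient on the
couch) it sees:

=========  =============  ====================================
angle(s)   class          shielding in the scatter path
=========  =============  ====================================
0°         head_rest      none (open head-rest side)
45°, 315°  head_gantry    partial gantry edge
90°, 270°  gantry         gantry body (strong attenuation)
135°, 225° couch_gantry   partial gantry edge, couch side
180°       couch          patient self-shielding along the couch
=========  =============  ====================================
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

__all__ = [
    "ADMISSIBLE_ANGLES",
    "WEEKS_PER_THREE_MONTHS",
    "DirectionClass",
    "DirectionLabel",
    "classify_direction",
    "inverse_square_scale",
    "WorkloadSummary",
    "BarrierSpec",
    "EvaluationPoint",
    "DoseResult",
    "MethodConfig",
]

ADMISSIBLE_ANGLES: tuple[int, ...] = (0, 45, 90, 135, 180, 225, 270, 315)

#: Weeks used when scaling a weekly dose to a 3-month evaluation period.
WEEKS_PER_THREE_MONTHS: float = 13.0


class DirectionClass(str, enum.Enum):
    HEAD_REST = "head_rest"
    HEAD_GANTRY = "head_gantry"
    GANTRY = "gantry"
    COUCH_GANTRY = "couch_gantry"
    COUCH = "couch"


_CLASS_BY_ANGLE: dict[int, DirectionClass] = {
    0: DirectionClass.HEAD_REST,
    45: DirectionClass.HEAD_GANTRY,
    315: DirectionClass.HEAD_GANTRY,
    90: DirectionClass.GANTRY,
    270: DirectionClass.GANTRY,
    135: DirectionClass.COUCH_GANTRY,
    225: DirectionClass.COUCH_GANTRY,
    180: DirectionClass.COUCH,
}

#: The five directions with little shielding between isocenter and wall
#: (everything except the gantry body and the patient's long axis).
LESS_SHIELDED_ANGLES: tuple[int, ...] = (0, 45, 135, 225, 315)


@dataclass(frozen=True)
class DirectionLabel:
    """One of the eight survey directions around the isocenter."""

    angle_deg: int

    def __post_init__(self) -> None:
        if self.angle_deg not in _CLASS_BY_ANGLE:
            raise ValueError(
                f"unknown direction angle {self.angle_deg}°; "
                f"admissible angles are {ADMISSIBLE_ANGLES}"
            )

    @property
    def direction_class(self) -> DirectionClass:
        return _CLASS_BY_ANGLE[self.angle_deg]

    @property
    def is_gantry(self) -> bool:
        return self.direction_class is DirectionClass.GANTRY

    @property
    def is_couch(self) -> bool:
        return self.direction_class is DirectionClass.COUCH


def classify_direction(angle_deg: int) -> DirectionLabel:
    """Map an angle in degrees to its :class:`DirectionLabel`.

    Raises ``ValueError`` for anything outside the eight admissible
    45°-step angles.
    """
    return DirectionLabel(int(angle_deg))


def inverse_square_scale(
    dose_at_ref: float, ref_distance_cm: float, target_distance_cm: float
) -> float:
    """Scale a dose from one distance to another by the inverse-square law.

    ``dose × (ref/target)²``; identity when the distances are equal.
    """
    if ref_distance_cm <= 0 or target_distance_cm <= 0:
        raise ValueError("distances must be positive")
    return dose_at_ref * (ref_distance_cm / target_distance_cm) ** 2


@dataclass(frozen=True)
class WorkloadSummary:
    """Workload of one scanner over one evaluation period.

    DLP values are in mGy·cm per period; the mAs workloads are optional
    because the DLP-based methods do not need them (only the Japanese
    conventional method does).
    """

    scanner_id: str
    dlp_head: float
    dlp_body: float
    workload_head_mAs: float | None = None
    workload_body_mAs: float | None = None
    period_weeks: float = 1.0
    contrast_counts_known: bool = True

    def __post_init__(self) -> None:
        if self.dlp_head < 0 or self.dlp_body < 0:
            raise ValueError(f"{self.scanner_id}: DLP must be non-negative")
        for w in (self.workload_head_mAs, self.workload_body_mAs):
            if w is not None and w < 0:
                raise ValueError(f"{self.scanner_id}: mAs workload must be non-negative")
        if self.period_weeks <= 0:
            raise ValueError("period_weeks must be positive")

    @property
    def dlp_total(self) -> float:
        return self.dlp_head + self.dlp_body

    @property
    def head_dlp_fraction(self) -> float:
        """Fraction of the total DLP delivered in head examinations."""
        if self.dlp_total == 0:
            raise ValueError("head fraction undefined for zero total DLP")
        return self.dlp_head / self.dlp_total

    @property
    def workload_total_mAs(self) -> float:
        """Total mAs workload; raises if either region's mAs is missing."""
        if self.workload_head_mAs is None or self.workload_body_mAs is None:
            raise ValueError(
                f"{self.scanner_id}: the JC method requires mAs workloads, "
                "but workload_head_mAs/workload_body_mAs are not set"
            )
        return self.workload_head_mAs + self.workload_body_mAs


@dataclass(frozen=True)
class BarrierSpec:
    """A shielding barrier and its transmission model.

    ``hvl`` attenuates as (1/2)^(t/half_value_mm); ``archer`` uses the
    three-parameter Archer fit [(1+β/α)·e^(αγt) − β/α]^(−1/γ) with α, β
    per mm and γ dimensionless.  Transmission is 1 at zero thickness and
    strictly decreasing in thickness for both models.
    """

    thickness_mm: float = 0.0
    model: str = "hvl"
    half_value_mm: float | None = None
    alpha: float | None = None
    beta: float | None = None
    gamma: float | None = None

    def __post_init__(self) -> None:
        if self.thickness_mm < 0:
            raise ValueError("barrier thickness must be non-negative")
        if self.model == "hvl":
            if self.half_value_mm is None or self.half_value_mm <= 0:
                raise ValueError("hvl model requires half_value_mm > 0")
        elif self.model == "archer":
            if self.alpha is None or self.beta is None or self.gamma is None:
                raise ValueError("archer model requires alpha, beta and gamma")
            if not all(map(math.isfinite, (self.alpha, self.beta, self.gamma))):
                raise ValueError("archer parameters must be finite")
            if self.alpha <= 0 or self.gamma <= 0:
                raise ValueError("archer model requires alpha > 0 and gamma > 0")
        else:
            raise ValueError(f"unknown transmission model {self.model!r}")


@dataclass(frozen=True)
class EvaluationPoint:
    """A point where the shielding requirement is evaluated."""

    direction: DirectionLabel
    distance_cm: float
    occupancy_T: float = 1.0
    barrier: BarrierSpec | None = None
    label: str | None = None

    def __post_init__(self) -> None:
        if self.distance_cm <= 0:
            raise ValueError("distance_cm must be positive")
        if not 0 < self.occupancy_T <= 1:
            raise ValueError("occupancy_T must lie in (0, 1]")


@dataclass(frozen=True)
class DoseResult:
    """Effective dose per period, split into physical components (mSv)."""

    primary: float = 0.0
    scatter: float = 0.0
    leakage: float = 0.0

    def __post_init__(self) -> None:
        for name in ("primary", "scatter", "leakage"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} component must be non-negative")

    @property
    def total_mSv(self) -> float:
        return self.primary + self.scatter + self.leakage

    @property
    def components(self) -> dict[str, float]:
        return {
            "primary": self.primary,
            "scatter": self.scatter,
            "leakage": self.leakage,
        }

    def __add__(self, other: "DoseResult") -> "DoseResult":
        return DoseResult(
            self.primary + other.primary,
            self.scatter + other.scatter,
            self.leakage + other.leakage,
        )

    def scaled(self, factor: float) -> "DoseResult":
        return DoseResult(
            self.primary * factor, self.scatter * factor, self.leakage * factor
        )


@dataclass(frozen=True)
class MethodConfig:
    """Constants of the DLP-based scatter engines.

    Defaults are the NCRP-DLP values: air kerma scatter factors
    κ_head = 9e-5 cm and κ_body = 3e-4 cm per unit DLP at 1 m, a 1.2
    constant on the body term, and E/Ka = 1.433 Sv/Gy to convert air
    kerma to effective dose.  The Japanese-DLP variant doubles κ and
    applies direction reduction factors 0.1 (gantry) and 0.4 (couch);
    use :meth:`japanese_dlp`.

    ``contrast_multiplier`` is the 1.4 safety factor recommended when
    the contrast/non-contrast examination split is unknown; it defaults
    to 1 because DLP summaries normally come from exposure reports with
    known counts.
    """

    kappa_head_cm: float = 9e-5
    kappa_body_cm: float = 3e-4
    body_constant: float = 1.2
    e_over_ka: float = 1.433
    kappa_multiplier: float = 1.0
    reduction_gantry: float = 1.0
    reduction_couch: float = 1.0
    contrast_multiplier: float = 1.0

    def __post_init__(self) -> None:
        for name in (
            "kappa_head_cm",
            "kappa_body_cm",
            "body_constant",
            "e_over_ka",
            "kappa_multiplier",
            "contrast_multiplier",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        for name in ("reduction_gantry", "reduction_couch"):
            if not 0 < getattr(self, name) <= 1:
                raise ValueError(f"{name} must lie in (0, 1]")

    @classmethod
    def ncrp_dlp(cls, **overrides) -> "MethodConfig":
        return cls(**overrides)

    @classmethod
    def japanese_dlp(cls, **overrides) -> "MethodConfig":
        """The proposed variant: doubled κ, reductions 0.1/0.4."""
        defaults = dict(kappa_multiplier=2.0, reduction_gantry=0.1, reduction_couch=0.4)
        defaults.update(overrides)
        return cls(**defaults)

    def reduction_for(self, direction: DirectionLabel) -> float:
        """Direction reduction factor: gantry/couch classes only."""
        if direction.is_gantry:
            return self.reduction_gantry
        if direction.is_couch:
            return self.reduction_couch
        return 1.0
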