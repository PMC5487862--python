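"""Barrier transmission and required-thickness solving.

The controlled-area boundary in Japan must stay below 1.3 mSv per
3 months.  Given an evaluated dose D for the period, the barrier must
transmit no more than ``limit/D`` (the required shielding ratio), and
the required thickness is the smallest t with transmission(t) ≤ that
ratio.  Both supported transmission models invert in closed form:

* hvl:    B(t) = (1/2)^(t/t_half)
* archer: B(t) = [(1+β/α)·e^(αγt) − β/α]^(−1/γ)

The Archer parameters shipped in :data:`ARCHER_PRESETS` are
illustrative broad-beam lead fits for typical CT tube potentials; they
are provided for demonstration and must be replaced by the user's own
jurisdiction/vendor data for real shielding design.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import pandas as pd

from .core import BarrierSpec, DoseResult, WEEKS_PER_THREE_MONTHS

__all__ = [
    "DoseConstraint",
    "transmission",
    "required_shielding_ratio",
    "required_thickness",
    "design_report",
    "weekly_to_three_months",
    "ARCHER_PRESETS",
]


@dataclass(frozen=True)
class DoseConstraint:
    """Dose limit at the area boundary, default 1.3 mSv per 3 months."""

    limit_mSv: float = 1.3
    period: str = "3 months"

    def __post_init__(self) -> None:
        if self.limit_mSv <= 0:
            raise ValueError("dose limit must be positive")


#: Illustrative broad-beam Archer fits for lead (per mm), synthetic
#: demonstration values in the range typical of 120–140 kV fits — NOT
#: normative data for shielding design.
ARCHER_PRESETS: dict[str, BarrierSpec] = {
    "lead-120kV-demo": BarrierSpec(model="archer", alpha=2.246, beta=5.73, gamma=0.547),
    "lead-140kV-demo": BarrierSpec(model="archer", alpha=2.009, beta=3.99, gamma=0.342),
}


def transmission(barrier: BarrierSpec, thickness_mm: float | None = None) -> float:
    """Air-kerma transmission of the barrier at a given thickness.

    Defaults to the barrier's own thickness.  Equals 1 at zero
    thickness and decreases strictly with t for both models.
    """
    t = barrier.thickness_mm if thickness_mm is None else thickness_mm
    if t < 0:
        raise ValueError("thickness must be non-negative")
    if barrier.model == "hvl":
        return 0.5 ** (t / barrier.half_value_mm)
    # archer
    a, b, g = barrier.alpha, barrier.beta, barrier.gamma
    return ((1.0 + b / a) * math.exp(a * g * t) - b / a) ** (-1.0 / g)


def required_shielding_ratio(
    evaluated_dose_mSv: float, constraint: DoseConstraint | None = None
) -> float:
    """Maximum admissible transmission: min(1, limit/dose).

    1 when the unshielded dose already meets the constraint (including
    the zero-dose case).
    """
    constraint = constraint or DoseConstraint()
    if evaluated_dose_mSv < 0:
        raise ValueError("evaluated dose must be non-negative")
    if evaluated_dose_mSv <= constraint.limit_mSv:
        return 1.0
    return constraint.limit_mSv / evaluated_dose_mSv


def required_thickness(ratio: float, barrier: BarrierSpec) -> float:
    """Smallest thickness (mm) with transmission ≤ ``ratio``.

    Closed-form inversion of the transmission model; 0 when ratio is 1.
    """
    if not 0 < ratio <= 1:
        raise ValueError("required ratio must lie in (0, 1]")
    if ratio == 1.0:
        return 0.0
    if barrier.model == "hvl":
        return barrier.half_value_mm * math.log2(1.0 / ratio)
    a, b, g = barrier.alpha, barrier.beta, barrier.gamma
    return math.log((ratio**-g + b / a) / (1.0 + b / a)) / (a * g)


def weekly_to_three_months(
    dose_mSv_per_week: float, weeks: float = WEEKS_PER_THREE_MONTHS
) -> float:
    """Scale a weekly dose to a 3-month evaluation period (default 13 weeks)."""
    if weeks <= 0:
        raise ValueError("weeks must be positive")
    return dose_mSv_per_week * weeks


def design_report(
    doses_by_method: Mapping[str, Mapping[str, float | DoseResult]],
    constraint: DoseConstraint | None = None,
    barrier: BarrierSpec | None = None,
    reference_method: str | None = None,
) -> pd.DataFrame:
    """Required shielding ratio and thickness per point and method.

    ``doses_by_method`` maps method name → {point label → dose for the
    evaluation period (mSv), either a number or a DoseResult}.  One row
    per (point, method) with the evaluated dose, required ratio,
    required thickness, and the thickness difference to the reference
    method ("Measured" when present, else the first method given).
    """
    constraint = constraint or DoseConstraint()
    if barrier is None:
        raise ValueError("design_report requires explicit barrier parameters")
    if not doses_by_method:
        raise ValueError("at least one method's doses are required")
    methods = list(doses_by_method)
    if reference_method is None:
        reference_method = "Measured" if "Measured" in methods else methods[0]
    if reference_method not in methods:
        raise ValueError(f"reference method {reference_method!r} not supplied")

    def _value(v: float | DoseResult) -> float:
        return v.total_mSv if isinstance(v, DoseResult) else float(v)

    thickness: dict[tuple[str, str], float] = {}
    rows = []
    for method in methods:
        for point, dose in doses_by_method[method].items():
            d = _value(dose)
            ratio = required_shielding_ratio(d, constraint)
            t = required_thickness(ratio, barrier)
            thickness[(method, point)] = t
            rows.append(
                {
                    "point": point,
                    "method": method,
                    "dose_mSv": d,
                    "required_ratio": ratio,
                    "required_thickness_mm": t,
                }
            )
    report = pd.DataFrame(rows)
    report["thickness_minus_reference_mm"] = [
        thickness[(r["method"], r["point"])]
        - thickness.get((reference_method, r["point"]), float("nan"))
        for _, r in report.iterrows()
    ]
    return report
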