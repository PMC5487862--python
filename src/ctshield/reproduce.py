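"""Recompute the published benchmark comparisons from the packaged data.

Everything here is derived at run time from the workload and survey
fixtures: calculated 1 m doses per scanner, calculated/measured ratio
tables for the NCRP-DLP and Japanese-DLP methods, and per-scanner
reduction factors.  Each ``reproduce_*`` function also reports whether
the recomputation stays within its regression tolerance against the
published reference values.

Tolerances reflect how the references were printed.  Reduction-factor
cells are pure ratios of doses printed with two decimals, so a
recomputed cell can differ from its printed value by up to ~1.5e-3
(three of 54 published cells round differently than the printed
inputs imply); summary statistics are required to match the printed
three decimals exactly.  Ratio-table means are compared at 10 %
relative: the inputs (workloads and doses) are table-rounded, which
moves individual ratios by several percent.  The published 135°
Japanese-DLP mean is additionally inconsistent with its own ×2
construction from the NCRP-DLP table, so the Japanese-DLP gate checks
the exact per-point multiplicative relation plus the 90° and pooled
means rather than every printed direction mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import DirectionLabel, EvaluationPoint, MethodConfig, WorkloadSummary
from .fixtures import (
    PaperFixture,
    TABLE4_NCRP_PRINTED,
    TABLE5_SUMMARY_PRINTED,
    TABLE6_JDLP_PRINTED,
    load_fixture,
)
from .methods import japanese_dlp_dose, ncrp_dlp_dose
from .survey import RatioTable, ratio_table, reduction_factors

__all__ = [
    "CELL_TOLERANCE",
    "MEAN_RTOL",
    "calculated_doses_1m",
    "fixture_ratio_table",
    "ReproductionResult",
    "reproduce_table4",
    "reproduce_table5",
    "reproduce_table6",
]

CELL_TOLERANCE = 1.5e-3  # reduction-factor cells, from 2-decimal printed doses
MEAN_RTOL = 0.10  # ratio-table means, from table-rounded inputs


def calculated_doses_1m(
    scanners: dict[str, WorkloadSummary], method: str = "ncrp-dlp"
) -> pd.DataFrame:
    """Calculated weekly dose at 1 m per scanner and direction (mSv)."""
    engine = {"ncrp-dlp": ncrp_dlp_dose, "jdlp": japanese_dlp_dose}[method]
    rows = []
    for sid, workload in scanners.items():
        for ang in (0, 45, 90, 135, 180, 225, 270, 315):
            point = EvaluationPoint(DirectionLabel(ang), distance_cm=100.0)
            rows.append(
                {
                    "scanner_id": sid,
                    "angle_deg": ang,
                    "dose_mSv": engine(workload, point).total_mSv,
                }
            )
    return pd.DataFrame(rows)


def fixture_ratio_table(fixture: PaperFixture, method: str = "ncrp-dlp") -> RatioTable:
    """Calculated/measured ratio table over the fixture's detected points."""
    calc = calculated_doses_1m(fixture.scanners, method)
    return ratio_table(calc, fixture.doses_1m, method=method)


@dataclass(frozen=True)
class ReproductionResult:
    table: pd.DataFrame
    within_tolerance: bool
    notes: str = ""


def reproduce_table5(fixture: PaperFixture | None = None) -> ReproductionResult:
    """Per-scanner gantry/couch reduction factors vs the published cells."""
    fixture = fixture or load_fixture()
    rf = reduction_factors(fixture.doses_1m)
    ref = fixture.reference_reduction
    computed = [
        float(rf.factors.loc[row["scanner_id"], row["angle_deg"]])
        for _, row in ref.iterrows()
    ]
    out = ref.copy()
    out = out.rename(columns={"factor": "published"})
    out["computed"] = computed
    out["abs_diff"] = (out["computed"] - out["published"]).abs()
    ok = bool((out["abs_diff"] <= CELL_TOLERANCE).all())

    summ = rf.summary
    checks = []
    for key, (mean, sd, mx) in TABLE5_SUMMARY_PRINTED.items():
        checks.append(round(float(summ.loc[key, "mean"]), 3) == mean)
        checks.append(round(float(summ.loc[key, "sd"]), 3) == sd)
        if mx is not None:
            checks.append(round(float(summ.loc[key, "max"]), 3) == mx)
    ok = ok and all(checks)
    return ReproductionResult(
        table=out,
        within_tolerance=ok,
        notes=f"max cell deviation {out['abs_diff'].max():.4f}",
    )


def _summary_with_reference(
    table: RatioTable, printed: dict[str, tuple[float, float]]
) -> pd.DataFrame:
    summ = table.direction_summary()
    summ["published_mean"] = [printed[idx][0] for idx in summ.index]
    summ["published_sd"] = [printed[idx][1] for idx in summ.index]
    summ["rel_dev"] = (summ["mean"] - summ["published_mean"]).abs() / summ[
        "published_mean"
    ]
    return summ


def reproduce_table4(fixture: PaperFixture | None = None) -> ReproductionResult:
    """NCRP-DLP/measured per-direction means vs the published summary."""
    fixture = fixture or load_fixture()
    table = fixture_ratio_table(fixture, "ncrp-dlp")
    summ = _summary_with_reference(table, TABLE4_NCRP_PRINTED)
    ok = bool((summ["rel_dev"] <= MEAN_RTOL).all())
    return ReproductionResult(
        table=summ,
        within_tolerance=ok,
        notes=f"max relative deviation {summ['rel_dev'].max():.3f}",
    )


def reproduce_table6(fixture: PaperFixture | None = None) -> ReproductionResult:
    """Japanese-DLP/measured ratios vs the published summary.

    Gates on the exact per-point ×{2, 0.2, 0.8} relation to the
    NCRP-DLP ratios plus the 90° and pooled means at 10 % relative (the
    printed 135° mean is inconsistent with the table's own
    construction; it is reported but not gated).
    """
    fixture = fixture or load_fixture()
    ncrp = fixture_ratio_table(fixture, "ncrp-dlp")
    jdlp = fixture_ratio_table(fixture, "jdlp")

    merged = ncrp.points.merge(
        jdlp.points, on=["scanner_id", "angle_deg"], suffixes=("_ncrp", "_jdlp")
    )
    expected_mult = merged["angle_deg"].map(
        lambda a: 0.2 if a in (90, 270) else (0.8 if a == 180 else 2.0)
    )
    pointwise_ok = bool(
        np.allclose(
            merged["ratio_jdlp"], merged["ratio_ncrp"] * expected_mult, rtol=1e-12
        )
    )

    summ = _summary_with_reference(jdlp, TABLE6_JDLP_PRINTED)
    gated = summ.loc[["90", "All"], "rel_dev"]
    ok = pointwise_ok and bool((gated <= MEAN_RTOL).all())
    return ReproductionResult(
        table=summ,
        within_tolerance=ok,
        notes=(
            f"pointwise ×(2/0.2/0.8) relation {'holds' if pointwise_ok else 'VIOLATED'}; "
            f"90° dev {summ.loc['90', 'rel_dev']:.3f}, "
            f"pooled dev {summ.loc['All', 'rel_dev']:.3f}"
        ),
    )
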