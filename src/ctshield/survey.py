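"""Analysis of measured dose surveys and calculated/measured comparisons.

The survey design this module processes: paired dosimeters on the walls
of a clinical CT room at the eight 45°-step directions, read out after
a one-week exposure period, background-subtracted, and normalised to
1 m from the isocenter with the inverse-square law.  Readings below the
dosimeter detection limit (0.01 mSv) are flagged non-detected and are
excluded from all ratio statistics rather than imputed.

Main products:

* per-scanner direction **reduction factors** — dose in a direction
  divided by the highest-direction dose of that scanner, quantifying
  gantry shielding (90°/270°) and patient self-shielding (180°);
* **ratio tables** of calculated over measured dose, with per-direction
  mean ± sample SD, pooled summary, minimum and underestimation counts;
* the head-examination-fraction correlation and plain two-sample
  t tests used to compare directions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import (
    ADMISSIBLE_ANGLES,
    LESS_SHIELDED_ANGLES,
    DirectionLabel,
    WorkloadSummary,
)

__all__ = [
    "DETECTION_LIMIT_mSv",
    "GANTRY_ANGLES",
    "COUCH_ANGLE",
    "SurveyRecord",
    "to_one_meter",
    "survey_frame",
    "ReductionFactors",
    "reduction_factors",
    "RatioTable",
    "ratio_table",
    "compare_methods",
    "CorrelationResult",
    "head_ratio_correlation",
    "two_sample_t",
]

#: OSL dosimeter detection limit after a one-week exposure (mSv).
DETECTION_LIMIT_mSv = 0.01

GANTRY_ANGLES = (90, 270)
COUCH_ANGLE = 180


@dataclass(frozen=True)
class SurveyRecord:
    """One dosimeter reading: net (background-subtracted) dose at a point."""

    scanner_id: str
    direction: DirectionLabel
    net_dose_mSv: float
    distance_cm: float
    detected: bool = True

    def __post_init__(self) -> None:
        if self.net_dose_mSv < 0:
            raise ValueError("net dose must be non-negative")
        if self.distance_cm <= 0:
            raise ValueError("distance must be positive")

    @classmethod
    def from_measurement(
        cls,
        scanner_id: str,
        angle_deg: int,
        net_dose_mSv: float,
        distance_cm: float,
        detection_limit_mSv: float = DETECTION_LIMIT_mSv,
    ) -> "SurveyRecord":
        """Build a record, flagging doses below the detection limit."""
        detected = net_dose_mSv >= detection_limit_mSv
        return cls(
            scanner_id,
            DirectionLabel(angle_deg),
            net_dose_mSv if detected else 0.0,
            distance_cm,
            detected,
        )


def to_one_meter(record: SurveyRecord) -> float:
    """Net dose converted to 1 m from the isocenter: dose × (d/100 cm)².

    Non-detected records carry no usable dose and are rejected; callers
    exclude them upstream.
    """
    if not record.detected:
        raise ValueError(
            f"{record.scanner_id} {record.direction.angle_deg}°: non-detected "
            "record has no quantifiable dose"
        )
    return record.net_dose_mSv * (record.distance_cm / 100.0) ** 2


def survey_frame(records: Iterable[SurveyRecord]) -> pd.DataFrame:
    """Long-format frame with columns scanner_id, angle_deg, distance_cm,
    detected, dose_1m_mSv (NaN for non-detected points)."""
    rows = []
    for r in records:
        rows.append(
            {
                "scanner_id": r.scanner_id,
                "angle_deg": r.direction.angle_deg,
                "distance_cm": r.distance_cm,
                "detected": r.detected,
                "dose_1m_mSv": to_one_meter(r) if r.detected else np.nan,
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class ReductionFactors:
    """Per-scanner direction factors and pooled gantry/couch summaries.

    ``factors`` is scanners × angles, each cell the 1 m dose in that
    direction divided by the scanner's highest-direction dose (so every
    row has exactly one 1.0).  ``summary`` has rows gantry (pooling 90°
    and 270°), couch (180°), and the two individual gantry angles, with
    mean, sample SD, min, max and n.
    """

    factors: pd.DataFrame
    summary: pd.DataFrame

    def pooled(self, which: str) -> float:
        return float(self.summary.loc[which, "mean"])


def _require_dose_frame(doses_1m) -> pd.DataFrame:
    if isinstance(doses_1m, pd.DataFrame):
        df = doses_1m.copy()
    else:
        df = survey_frame(doses_1m)
    needed = {"scanner_id", "angle_deg", "dose_1m_mSv"}
    missing = needed - set(df.columns)
    if missing:
        raise ValueError(f"dose frame is missing columns {sorted(missing)}")
    if "detected" in df.columns:
        df = df[df["detected"]]
    return df.dropna(subset=["dose_1m_mSv"])


def reduction_factors(doses_1m) -> ReductionFactors:
    """Direction reduction factors from 1 m-normalised doses.

    Accepts a frame (scanner_id, angle_deg, dose_1m_mSv[, detected]) or
    an iterable of detected :class:`SurveyRecord`.  Scanners with fewer
    than two detected directions cannot define a ratio and are dropped.
    """
    df = _require_dose_frame(doses_1m)
    wide = df.pivot_table(
        index="scanner_id", columns="angle_deg", values="dose_1m_mSv", aggfunc="mean"
    )
    enough = wide.notna().sum(axis=1) >= 2
    if not enough.all():
        import warnings

        dropped = list(wide.index[~enough])
        warnings.warn(f"scanners without ≥2 detected directions excluded: {dropped}")
        wide = wide[enough]
    factors = wide.div(wide.max(axis=1), axis=0)

    def _summ(values: np.ndarray) -> dict[str, float]:
        values = values[~np.isnan(values)]
        return {
            "mean": float(np.mean(values)),
            "sd": float(np.std(values, ddof=1)) if len(values) > 1 else np.nan,
            "min": float(np.min(values)),
            "max": float(np.max(values)),
            "n": len(values),
        }

    summary_rows = {}
    gantry_vals = []
    for ang in GANTRY_ANGLES:
        if ang in factors.columns:
            vals = factors[ang].to_numpy(dtype=float)
            summary_rows[str(ang)] = _summ(vals)
            gantry_vals.append(vals[~np.isnan(vals)])
    if gantry_vals:
        summary_rows["gantry"] = _summ(np.concatenate(gantry_vals))
    if COUCH_ANGLE in factors.columns:
        summary_rows["couch"] = _summ(factors[COUCH_ANGLE].to_numpy(dtype=float))
    summary = pd.DataFrame(summary_rows).T
    return ReductionFactors(factors=factors, summary=summary)


@dataclass(frozen=True)
class RatioTable:
    """Calculated/measured dose ratios over detected survey points."""

    points: pd.DataFrame  # columns scanner_id, angle_deg, ratio
    method: str = ""

    def direction_summary(self) -> pd.DataFrame:
        """Per-direction mean ± sample SD and n, plus a pooled 'All' row."""
        grouped = self.points.groupby("angle_deg")["ratio"]
        out = grouped.agg(mean="mean", sd=lambda s: s.std(ddof=1), n="count")
        out.index = out.index.astype(str)
        pooled = self.points["ratio"]
        out.loc["All"] = {
            "mean": pooled.mean(),
            "sd": pooled.std(ddof=1),
            "n": len(pooled),
        }
        out["n"] = out["n"].astype(int)
        return out

    def min_ratio(self) -> float:
        return float(self.points["ratio"].min())

    def underestimation(self) -> pd.DataFrame:
        """Count and fraction of ratios < 1, over all detected points and
        over the five less-shielded directions (0°, 45°, 135°, 225°, 315°)."""
        rows = {}
        all_pts = self.points
        less = all_pts[all_pts["angle_deg"].isin(LESS_SHIELDED_ANGLES)]
        for name, sub in (("all", all_pts), ("less_shielded", less)):
            n_under = int((sub["ratio"] < 1).sum())
            rows[name] = {
                "n_underestimated": n_under,
                "n_points": len(sub),
                "fraction": n_under / len(sub) if len(sub) else np.nan,
            }
        return pd.DataFrame(rows).T


def ratio_table(
    calculated: Mapping[tuple[str, int], float] | pd.DataFrame,
    survey,
    method: str = "",
) -> RatioTable:
    """Per-point calculated/measured ratios over the detected survey points.

    ``calculated`` maps (scanner_id, angle_deg) to a calculated dose, or
    is a frame with those columns plus ``dose_mSv``; ``survey`` provides
    measured doses at the same reference distance (the ratio is
    distance-independent as long as both sides share the reference).
    Detected survey points with no calculated partner are an error.
    """
    measured = _require_dose_frame(survey)
    if isinstance(calculated, pd.DataFrame):
        calc_map = {
            (str(r["scanner_id"]), int(r["angle_deg"])): float(r["dose_mSv"])
            for _, r in calculated.iterrows()
        }
    else:
        calc_map = {(str(k[0]), int(k[1])): float(v) for k, v in calculated.items()}

    missing = [
        key
        for key in (
            (str(r["scanner_id"]), int(r["angle_deg"])) for _, r in measured.iterrows()
        )
        if key not in calc_map
    ]
    if missing:
        raise KeyError(f"no calculated dose for survey points: {sorted(set(missing))}")

    rows = [
        {
            "scanner_id": str(r["scanner_id"]),
            "angle_deg": int(r["angle_deg"]),
            "ratio": calc_map[(str(r["scanner_id"]), int(r["angle_deg"]))]
            / float(r["dose_1m_mSv"]),
        }
        for _, r in measured.iterrows()
    ]
    return RatioTable(points=pd.DataFrame(rows), method=method)


def compare_methods(table_a: RatioTable, table_b: RatioTable) -> pd.DataFrame:
    """Per-direction ratio of mean ratios (A/B) plus the pooled value."""
    a = table_a.direction_summary()["mean"]
    b = table_b.direction_summary()["mean"]
    if set(a.index) != set(b.index):
        raise ValueError("ratio tables cover different directions")
    out = pd.DataFrame({"mean_a": a, "mean_b": b})
    zero = out["mean_b"] == 0
    out["a_over_b"] = np.where(zero, np.nan, out["mean_a"] / out["mean_b"])
    if zero.any():
        import warnings

        warnings.warn("zero denominator mean in compare_methods; ratio set to NaN")
    return out


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p: float
    n: int

    @property
    def abs_r(self) -> float:
        return abs(self.r)


def head_ratio_correlation(
    workloads: Mapping[str, WorkloadSummary] | Sequence[WorkloadSummary],
    table: RatioTable,
    direction: DirectionLabel,
) -> CorrelationResult:
    """Pearson correlation of head-DLP fraction vs calculated/measured ratio.

    The head fraction is dlp_head/(dlp_head+dlp_body) per scanner; the
    ratio is taken at the requested direction.  Reports signed r with a
    two-sided p value (the magnitude is available as ``abs_r``).
    """
    if not isinstance(workloads, Mapping):
        workloads = {w.scanner_id: w for w in workloads}
    sub = table.points[table.points["angle_deg"] == direction.angle_deg]
    pairs = [
        (workloads[sid].head_dlp_fraction, ratio)
        for sid, ratio in zip(sub["scanner_id"], sub["ratio"])
        if sid in workloads
    ]
    if len(pairs) < 3:
        raise ValueError("at least 3 paired observations are required")
    x, y = map(np.asarray, zip(*pairs))
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for constant input")
    res = stats.pearsonr(x, y)
    return CorrelationResult(r=float(res.statistic), p=float(res.pvalue), n=len(pairs))


def two_sample_t(group_a, group_b) -> tuple[float, float]:
    """Equal-variance two-sample Student t test, two-sided p."""
    a = np.asarray(list(group_a), dtype=float)
    b = np.asarray(list(group_b), dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least two observations")
    res = stats.ttest_ind(a, b, equal_var=True)
    return float(res.statistic), float(res.pvalue)
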