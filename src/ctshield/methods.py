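"""The three scatter-dose calculation engines.

* :func:`ncrp_dlp_dose` — DLP-based estimate: scattered air kerma at the
  evaluation point is κ·DLP·(100/d)² with separate head and body terms
  (the body term carries a 1.2 constant), converted to effective dose
  with E/Ka.
* :func:`japanese_dlp_dose` — the proposed variant: κ doubled for
  safety, with direction reduction factors 0.1 (gantry) and 0.4 (couch)
  recognising gantry and patient self-shielding.
* :func:`jc_total` — the Japanese conventional (mAs-workload) method:
  primary, scatter and leakage components evaluated at four X-ray tube
  positions (0°, 90°, 180°, 270°) and summed.

All engines return a :class:`~ctshield.core.DoseResult` whose components
sum to the total, are linear (degree-1 homogeneous) in workload, and
scale with the inverse square of distance.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from .core import (
    BarrierSpec,
    DoseResult,
    EvaluationPoint,
    MethodConfig,
    WorkloadSummary,
)
from .shielding import transmission

__all__ = [
    "TUBE_POSITION_ANGLES",
    "TubePosition",
    "JCParams",
    "PositionGeometry",
    "ncrp_dlp_dose",
    "japanese_dlp_dose",
    "jc_primary",
    "jc_scatter",
    "jc_leakage",
    "jc_total",
]

TUBE_POSITION_ANGLES: tuple[int, ...] = (0, 90, 180, 270)


@dataclass(frozen=True)
class TubePosition:
    """One of the four tube angles the JC method evaluates (up/right/down/left)."""

    angle_deg: int

    def __post_init__(self) -> None:
        if self.angle_deg not in TUBE_POSITION_ANGLES:
            raise ValueError(
                f"tube position must be one of {TUBE_POSITION_ANGLES}, "
                f"got {self.angle_deg}"
            )


def _dlp_air_kerma_at_1m(workload: WorkloadSummary, config: MethodConfig) -> float:
    """Scattered air kerma (mGy) at 1 m per period from the DLP workload."""
    head = config.kappa_head_cm * workload.dlp_head
    body = config.body_constant * config.kappa_body_cm * workload.dlp_body
    return config.kappa_multiplier * (head + body)


def ncrp_dlp_dose(
    workload: WorkloadSummary,
    point: EvaluationPoint,
    config: MethodConfig | None = None,
) -> DoseResult:
    """Scattered effective dose at a point by the DLP-based method.

    Head and body contributions are calculated separately and summed:

        scatter = m·[κ_head·DLP_head + 1.2·κ_body·DLP_body]
                  · c · (E/Ka) · (100/d_cm)² · T · r(direction)

    where m is the κ multiplier (1; 2 for the Japanese-DLP variant),
    c the contrast multiplier and r the direction reduction factor
    (1 except for gantry/couch classes under Japanese-DLP).  The result
    has only a scatter component; primary and leakage are zero.
    """
    config = config or MethodConfig()
    contrast = config.contrast_multiplier
    if not workload.contrast_counts_known and contrast == 1.0:
        # safety factor when the contrast / non-contrast split is unknown
        contrast = 1.4
    kerma = _dlp_air_kerma_at_1m(workload, config)
    scatter = (
        kerma
        * contrast
        * config.e_over_ka
        * (100.0 / point.distance_cm) ** 2
        * point.occupancy_T
        * config.reduction_for(point.direction)
    )
    return DoseResult(scatter=scatter)


def japanese_dlp_dose(
    workload: WorkloadSummary,
    point: EvaluationPoint,
    config: MethodConfig | None = None,
) -> DoseResult:
    """Scattered effective dose by the proposed Japanese-DLP method.

    Identical to :func:`ncrp_dlp_dose` with κ doubled and direction
    reduction factors 0.1 (90°/270°) and 0.4 (180°); directions without
    gantry or patient shielding get exactly twice the NCRP-DLP dose.
    """
    return ncrp_dlp_dose(workload, point, config or MethodConfig.japanese_dlp())


@dataclass(frozen=True)
class JCParams:
    """Source terms and geometry of the Japanese conventional method.

    ``x_per_mAs`` is the air kerma per mAs at 1 m from the tube focus
    (mGy·m²/mAs); ``scatter_fraction_a`` the scatter fraction scaled to
    d3 = 1 m and a 400 cm² field; ``field_F_cm2`` the exposure field;
    ``leakage_rate_XL`` the housing leakage air-kerma rate at 1 m
    (mGy·m²/h, 1.0 by regulation); ``beam_on_time_h`` the beam-on hours
    per period.  Distances d1–d4 are in meters (d1: focus→point, d2:
    patient→point, d3: focus→patient, d4: focus→point for leakage).
    The CT gantry in the primary-beam path is taken as 2.5 mm lead
    equivalent, attenuated with ``lead_half_value_mm``.
    """

    x_per_mAs: float
    scatter_fraction_a: float
    field_F_cm2: float
    beam_on_time_h: float = 0.0
    leakage_rate_XL: float = 1.0
    gantry_lead_equiv_mm: float = 2.5
    lead_half_value_mm: float = 0.25
    d1_m: float = 1.0
    d2_m: float = 1.0
    d3_m: float = 1.0
    d4_m: float = 1.0
    use_factor_U: float = 1.0

    def __post_init__(self) -> None:
        positive = (
            "x_per_mAs",
            "scatter_fraction_a",
            "field_F_cm2",
            "leakage_rate_XL",
            "lead_half_value_mm",
            "d1_m",
            "d2_m",
            "d3_m",
            "d4_m",
            "use_factor_U",
        )
        for name in positive:
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.beam_on_time_h < 0 or self.gantry_lead_equiv_mm < 0:
            raise ValueError("beam_on_time_h and gantry_lead_equiv_mm must be ≥ 0")


@dataclass(frozen=True)
class PositionGeometry:
    """Per-tube-position override of the JC distances (meters)."""

    d1_m: float
    d2_m: float
    d3_m: float = 1.0
    d4_m: float | None = None  # defaults to d1

    @property
    def leakage_distance_m(self) -> float:
        return self.d4_m if self.d4_m is not None else self.d1_m


def _barrier_transmission(barrier: BarrierSpec | None) -> float:
    return 1.0 if barrier is None else transmission(barrier)


def jc_primary(
    params: JCParams,
    workload_mAs: float,
    config: MethodConfig | None = None,
    barrier: BarrierSpec | None = None,
    d1_m: float | None = None,
    occupancy_T: float = 1.0,
    gantry_lead_equiv_mm: float | None = None,
) -> float:
    """Primary-beam effective dose (mSv): X·Dt·W·(E/Ka)·U·T / d1².

    Dt combines the barrier transmission with the gantry's lead
    equivalence (the CT primary beam always terminates in the gantry/
    detector assembly; pass ``gantry_lead_equiv_mm=0`` for an open
    beam).
    """
    config = config or MethodConfig()
    if workload_mAs < 0:
        raise ValueError("workload must be non-negative")
    d1 = params.d1_m if d1_m is None else d1_m
    if d1 <= 0:
        raise ValueError("d1 must be positive")
    equiv = (
        params.gantry_lead_equiv_mm
        if gantry_lead_equiv_mm is None
        else gantry_lead_equiv_mm
    )
    dt = _barrier_transmission(barrier)
    if equiv > 0:
        dt *= 0.5 ** (equiv / params.lead_half_value_mm)
    return (
        params.x_per_mAs
        * dt
        * workload_mAs
        * config.e_over_ka
        * params.use_factor_U
        * occupancy_T
        / d1**2
    )


def jc_scatter(
    params: JCParams,
    workload_mAs: float,
    config: MethodConfig | None = None,
    barrier: BarrierSpec | None = None,
    d2_m: float | None = None,
    d3_m: float | None = None,
    occupancy_T: float = 1.0,
) -> float:
    """Patient-scatter effective dose (mSv).

    X·Dt·W·(E/Ka)·U·T / (d2²·d3²) × a·F/400, with the scatter fraction
    ``a`` normalised to a 400 cm² field at d3 = 1 m.
    """
    config = config or MethodConfig()
    if workload_mAs < 0:
        raise ValueError("workload must be non-negative")
    d2 = params.d2_m if d2_m is None else d2_m
    d3 = params.d3_m if d3_m is None else d3_m
    if d2 <= 0 or d3 <= 0:
        raise ValueError("d2 and d3 must be positive")
    return (
        params.x_per_mAs
        * _barrier_transmission(barrier)
        * workload_mAs
        * config.e_over_ka
        * params.use_factor_U
        * occupancy_T
        / (d2**2 * d3**2)
        * params.scatter_fraction_a
        * params.field_F_cm2
        / 400.0
    )


def jc_leakage(
    params: JCParams,
    config: MethodConfig | None = None,
    barrier: BarrierSpec | None = None,
    d4_m: float | None = None,
    occupancy_T: float = 1.0,
) -> float:
    """Tube-housing leakage effective dose (mSv).

    X_L·tw·(E/Ka)·U·T / d4² × (1/2)^(t/t_half).  The half-value
    attenuation uses the barrier's ``half_value_mm`` (an hvl-model
    barrier is required when a barrier is given).
    """
    config = config or MethodConfig()
    d4 = params.d4_m if d4_m is None else d4_m
    if d4 <= 0:
        raise ValueError("d4 must be positive")
    atten = 1.0
    if barrier is not None:
        if barrier.model != "hvl":
            raise ValueError("leakage attenuation requires an hvl-model barrier")
        if barrier.half_value_mm is None or barrier.half_value_mm <= 0:
            raise ValueError("half-value thickness must be positive")
        atten = 0.5 ** (barrier.thickness_mm / barrier.half_value_mm)
    return (
        params.leakage_rate_XL
        * params.beam_on_time_h
        * config.e_over_ka
        * params.use_factor_U
        * occupancy_T
        / d4**2
        * atten
    )


def jc_total(
    params: JCParams,
    workload: WorkloadSummary,
    point: EvaluationPoint | None = None,
    config: MethodConfig | None = None,
    geometry: dict[int, PositionGeometry] | None = None,
    barrier: BarrierSpec | None = None,
) -> DoseResult:
    """Sum the JC components over the four tube positions.

    ``geometry`` maps tube angles to per-position distances; positions
    without an entry fall back to the distances in ``params`` (or, when
    an :class:`EvaluationPoint` is given and the params distances were
    left at their defaults, to the point's distance for d1/d2/d4 with
    d3 = 1 m).  Beam-on time is not apportioned per position: the full
    workload and beam time are charged at every position, the
    conventional (conservative) reading.
    """
    config = config or MethodConfig()
    workload_mAs = workload.workload_total_mAs  # raises with guidance if absent
    occupancy = 1.0
    eff_params = params
    if point is not None:
        occupancy = point.occupancy_T
        d_m = point.distance_cm / 100.0
        if (params.d1_m, params.d2_m, params.d4_m) == (1.0, 1.0, 1.0):
            eff_params = replace(params, d1_m=d_m, d2_m=d_m, d4_m=d_m)
        if barrier is None:
            barrier = point.barrier

    total = DoseResult()
    for angle in TUBE_POSITION_ANGLES:
        geo = (geometry or {}).get(angle)
        d1 = geo.d1_m if geo else None
        d2 = geo.d2_m if geo else None
        d3 = geo.d3_m if geo else None
        d4 = geo.leakage_distance_m if geo else None
        total = total + DoseResult(
            primary=jc_primary(
                eff_params, workload_mAs, config, barrier, d1, occupancy
            ),
            scatter=jc_scatter(
                eff_params, workload_mAs, config, barrier, d2, d3, occupancy
            ),
            leakage=jc_leakage(eff_params, config, barrier, d4, occupancy),
        )
    return total
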