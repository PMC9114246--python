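"""Scale-up correlations for geometrically similar stirred fermenters.

The strategy is constant specific power (P/V_w) under geometric similarity,
the customary choice for ungassed anaerobic broths. Two power laws carry it:

* specific power transfers as (P/V)₂ = (P/V)₁ · (V₁/V₂)^α with α = 0.37,
  an empirical cross-plant exponent;
* the agitation speed follows from P = Po·ρ·N³·D⁵ as
  N₂ = N₁ · (V₂/V₁)^β · (D₁/D₂)^γ with β = 0.21 and γ = 5/3.

Both routes are computed and reported side by side. They do not agree
exactly — the speed route then re-evaluates the physical power law at N₂,
the α route extrapolates a measured intensity — and the discrepancy is a
diagnostic, deliberately surfaced rather than averaged away.

The stage count n of a multi-impeller shaft is bracketed by the liquid
height: (Z − 2D)/(2D) < n < (Z − D)/D, i.e. each impeller needs between
one and two diameters of liquid around it.
"""

from __future__ import annotations

import math
from typing import Optional

from pydantic import BaseModel, ConfigDict, Field, model_validator

from .core import FermenterCase, SimilarityRecord
from .hydrodynamics import (
    OperatingPoint,
    PowerCorrelation,
    DEFAULT_CORRELATION,
    evaluate_operating_point,
)

__all__ = [
    "ScaleUpSpec",
    "ScaleUpResult",
    "scale_specific_power",
    "scale_impeller_speed",
    "impeller_count_bounds",
    "feasible_impeller_counts",
    "run_scaleup",
    "DEFAULT_PV_EXPONENT",
    "DEFAULT_SPEED_VOLUME_EXPONENT",
    "DEFAULT_SPEED_DIAMETER_EXPONENT",
    "DEFAULT_COUNT_TOLERANCE",
]

DEFAULT_PV_EXPONENT = 0.37
DEFAULT_SPEED_VOLUME_EXPONENT = 0.21
DEFAULT_SPEED_DIAMETER_EXPONENT = 5.0 / 3.0
#: Slack on the upper impeller-count bound; engineering practice admits a
#: count sitting a few percent above the strict (Z − D)/D limit.
DEFAULT_COUNT_TOLERANCE = 0.1


class ScaleUpSpec(BaseModel):
    """Source and target cases plus the scale-up exponents."""

    model_config = ConfigDict(frozen=True)

    source: FermenterCase
    target: FermenterCase
    pv_exponent: float = Field(default=DEFAULT_PV_EXPONENT, gt=0)
    speed_volume_exponent: float = Field(default=DEFAULT_SPEED_VOLUME_EXPONENT, gt=0)
    speed_diameter_exponent: float = Field(
        default=DEFAULT_SPEED_DIAMETER_EXPONENT, gt=0
    )
    count_tolerance: float = Field(default=DEFAULT_COUNT_TOLERANCE, ge=0)

    @model_validator(mode="after")
    def _check(self) -> "ScaleUpSpec":
        # identical volumes are allowed only for the degenerate identity case
        return self


class ScaleUpResult(BaseModel):
    """Outcome of one scale-up step.

    ``operating_point`` is the target state at the scaled speed with the
    selected stage count. ``pv_predicted`` is the α-route extrapolation of
    the source specific power; ``pv_discrepancy_percent`` quantifies how far
    the physical power law at N₂ lands from it.
    """

    model_config = ConfigDict(frozen=True)

    target_speed: float = Field(gt=0)
    operating_point: OperatingPoint
    n_impellers: int = Field(ge=1)
    feasible_counts: tuple[int, ...]
    pv_predicted: float = Field(gt=0, description="W m⁻³, α-route")
    pv_discrepancy_percent: float
    similarity: Optional[SimilarityRecord] = None


def scale_specific_power(
    pv1: float, Vw1: float, Vw2: float, alpha: float = DEFAULT_PV_EXPONENT
) -> float:
    """Transfer a specific power across scales: pv₂ = pv₁·(V₁/V₂)^α."""
    for name, v in (("pv1", pv1), ("Vw1", Vw1), ("Vw2", Vw2), ("alpha", alpha)):
        if v <= 0:
            raise ValueError(f"{name} must be positive, got {v}")
    return pv1 * (Vw1 / Vw2) ** alpha


def scale_impeller_speed(
    N1: float,
    Vw1: float,
    Vw2: float,
    D1: float,
    D2: float,
    beta: float = DEFAULT_SPEED_VOLUME_EXPONENT,
    gamma: float = DEFAULT_SPEED_DIAMETER_EXPONENT,
) -> float:
    """Scaled agitation speed N₂ = N₁·(V₂/V₁)^β·(D₁/D₂)^γ."""
    for name, v in (
        ("N1", N1), ("Vw1", Vw1), ("Vw2", Vw2), ("D1", D1), ("D2", D2),
    ):
        if v <= 0:
            raise ValueError(f"{name} must be positive, got {v}")
    return N1 * (Vw2 / Vw1) ** beta * (D1 / D2) ** gamma


def impeller_count_bounds(Z: float, D: float) -> tuple[float, float]:
    """Open bounds on the stage count: ((Z − 2D)/(2D), (Z − D)/D)."""
    if D <= 0:
        raise ValueError("D must be positive")
    if Z <= D:
        raise ValueError(
            f"liquid height Z = {Z:g} m does not accommodate any impeller of "
            f"diameter D = {D:g} m"
        )
    return (Z - 2.0 * D) / (2.0 * D), (Z - D) / D


def feasible_impeller_counts(
    Z: float, D: float, tolerance: float = DEFAULT_COUNT_TOLERANCE
) -> set[int]:
    """Integer stage counts compatible with the liquid height.

    The strict interval is opened by ``tolerance`` at the top:
    {n ∈ ℤ : lower < n ≤ upper + τ}. τ = 0.1 admits the marginal fits an
    engineer would accept (e.g. 2 stages where (Z − D)/D = 1.95).
    """
    lower, upper = impeller_count_bounds(Z, D)
    lo = max(1, math.floor(lower) + 1)
    hi = math.floor(upper + tolerance)
    counts = {n for n in range(lo, hi + 1) if n > lower}
    if not counts:
        raise ValueError(
            f"no integer impeller count fits Z = {Z:g} m, D = {D:g} m "
            f"(bounds {lower:.3g}..{upper:.3g}, tolerance {tolerance})"
        )
    return counts


def run_scaleup(
    spec: ScaleUpSpec,
    *,
    correlation: PowerCorrelation = DEFAULT_CORRELATION,
) -> ScaleUpResult:
    """Execute one scale-up step from ``spec.source`` to ``spec.target``.

    Pipeline: scaled speed N₂ (β/γ power law) → feasible stage counts from
    the target's similarity-derived liquid height (falling back to the
    as-built height) → maximum feasible count → power-law power at N₂ →
    derived specific power, dissipation, microscale and torque, all
    recorded on the target operating point.
    """
    src, tgt = spec.source, spec.target
    N2 = scale_impeller_speed(
        src.nominal_speed,
        src.vessel.working_volume,
        tgt.vessel.working_volume,
        src.impeller.diameter,
        tgt.impeller.diameter,
        spec.speed_volume_exponent,
        spec.speed_diameter_exponent,
    )
    Z = tgt.vessel.calculated_working_height or tgt.vessel.actual_working_height
    if Z > tgt.impeller.diameter:
        counts = feasible_impeller_counts(
            Z, tgt.impeller.diameter, spec.count_tolerance
        )
        n = max(counts)
    else:
        counts, n = {tgt.impeller.count}, tgt.impeller.count
    op = evaluate_operating_point(
        tgt, N2, n_impellers=n, basis="working", correlation=correlation
    )
    src_op = evaluate_operating_point(src, basis="working", correlation=correlation)
    pv_pred = scale_specific_power(
        src_op.specific_power,
        src.vessel.working_volume,
        tgt.vessel.working_volume,
        spec.pv_exponent,
    )
    disc = 100.0 * (op.specific_power - pv_pred) / pv_pred
    return ScaleUpResult(
        target_speed=N2,
        operating_point=op,
        n_impellers=n,
        feasible_counts=tuple(sorted(counts)),
        pv_predicted=pv_pred,
        pv_discrepancy_percent=disc,
    )
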