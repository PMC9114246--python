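"""Domain types and geometric bookkeeping for stirred-tank fermenters.

The objects here describe one fermenter "case" — the broth, the vessel and
the agitator — at a single scale, plus the geometric-similarity arithmetic
used when a laboratory or pilot vessel is projected to an industrial one.
All quantities are SI internally: metres, seconds, kilograms, watts.
Rotational speed is stored in s⁻¹ (revolutions per second); rpm appears only
at interfaces.
"""

from __future__ import annotations

import enum
import math
import warnings
from typing import Optional

from pydantic import BaseModel, ConfigDict, Field, model_validator

__all__ = [
    "ImpellerType",
    "Fluid",
    "VesselGeometry",
    "Impeller",
    "FermenterCase",
    "SimilarityRecord",
    "total_solids_percent",
    "derive_geometry",
    "calculated_working_height",
    "similarity_ratio",
    "apply_similarity_ratio",
    "occupancy_percent",
    "geometric_scale_factor",
    "OCCUPANCY_WARNING_THRESHOLD",
]

#: Below this fraction of the actual working height, a vessel is flagged as
#: under-filled relative to common practice (working volume ~80% of total).
OCCUPANCY_WARNING_THRESHOLD = 0.80


class ImpellerType(str, enum.Enum):
    """Commercial turbine designs commonly used for fermentation broths."""

    RTB = "RTB"  #: Rushton turbine blade (radial disc turbine)
    CBT = "CBT"  #: concave blade turbine
    PBT = "PBT"  #: pitched blade turbine
    LA310 = "LA310"  #: Lightnin A310 three-blade hydrofoil
    LA315 = "LA315"  #: Lightnin A315 four-blade hydrofoil
    MP = "MP"  #: marine propeller (1.0 pitch)


class Fluid(BaseModel):
    """Fermentation broth properties.

    Parameters
    ----------
    density : float
        ρ, kg m⁻³.
    dynamic_viscosity : float
        μ, Pa·s (kg m⁻¹ s⁻¹).
    kinematic_viscosity : float, optional
        ν, m² s⁻¹. May be supplied (e.g. a separately rounded measured
        value) or derived as μ/ρ. When supplied it must agree with μ/ρ to
        within 2% — independently rounded printed values typically differ
        in the last digit.
    cell_size_range : (float, float), optional
        Min/max microbial cell length in µm, used for shear screening.
    """

    model_config = ConfigDict(frozen=True)

    density: float = Field(gt=0)
    dynamic_viscosity: float = Field(gt=0)
    kinematic_viscosity: Optional[float] = Field(default=None, gt=0)
    cell_size_range: Optional[tuple[float, float]] = None

    @model_validator(mode="after")
    def _check_consistency(self) -> "Fluid":
        if self.kinematic_viscosity is not None:
            derived = self.dynamic_viscosity / self.density
            rel = abs(self.kinematic_viscosity - derived) / self.kinematic_viscosity
            if rel > 0.02:
                raise ValueError(
                    f"kinematic_viscosity {self.kinematic_viscosity:g} m²/s disagrees "
                    f"with dynamic_viscosity/density = {derived:g} m²/s by {rel:.1%} (>2%)"
                )
        if self.cell_size_range is not None:
            lo, hi = self.cell_size_range
            if not (0 < lo <= hi):
                raise ValueError("cell_size_range must satisfy 0 < min <= max")
        return self

    @property
    def nu(self) -> float:
        """Kinematic viscosity in m² s⁻¹ (stored value, else μ/ρ)."""
        if self.kinematic_viscosity is not None:
            return self.kinematic_viscosity
        return self.dynamic_viscosity / self.density


class VesselGeometry(BaseModel):
    """Cylindrical stirred-tank dimensions and dimensionless ratios.

    Volumes are independent inputs — they are *not* recomputed from
    π/4·T²·Z because heads and freeboard are not modelled.

    Attributes
    ----------
    total_volume, working_volume : float
        V_t and V_w in m³ (V_w ≤ V_t).
    tank_diameter : float
        T, m.
    total_height : float
        H, m.
    actual_working_height : float
        Z₀, m — the as-built liquid height.
    calculated_working_height : float, optional
        Z, m — the similarity-derived liquid height; may exceed or fall
        short of Z₀.
    D_over_T, H_over_T, Z_over_T : float
        The dimensionless design ratios (Z_over_T refers to Z₀/T).
    """

    model_config = ConfigDict(frozen=True)

    total_volume: float = Field(gt=0)
    working_volume: float = Field(gt=0)
    tank_diameter: float = Field(gt=0)
    total_height: float = Field(gt=0)
    actual_working_height: float = Field(gt=0)
    calculated_working_height: Optional[float] = Field(default=None, gt=0)
    D_over_T: float = Field(gt=0)
    H_over_T: float = Field(gt=0)
    Z_over_T: float = Field(gt=0)

    @model_validator(mode="after")
    def _check(self) -> "VesselGeometry":
        if self.working_volume > self.total_volume * (1 + 1e-9):
            raise ValueError(
                f"working_volume {self.working_volume} m³ exceeds "
                f"total_volume {self.total_volume} m³"
            )
        implied_T = self.actual_working_height / self.Z_over_T
        if abs(implied_T - self.tank_diameter) / self.tank_diameter > 0.005:
            raise ValueError(
                f"tank_diameter {self.tank_diameter:g} m inconsistent with "
                f"Z0/(Z/T) = {implied_T:g} m (>0.5%)"
            )
        return self


class Impeller(BaseModel):
    """An agitator: type, turbulent power number, diameter and stage count.

    ``turbulent_power_number`` is the constant Po reached above Re ≈ 10⁴.
    ``effective_power_number``, when set, is a chart-read Po valid at the
    case's own (transition-regime) operating point and takes precedence
    there; this is how the laboratory-scale fixture (Re ≈ 1.8×10³) is
    encoded.
    """

    model_config = ConfigDict(frozen=True)

    type_id: ImpellerType
    turbulent_power_number: float = Field(gt=0)
    diameter: float = Field(gt=0)
    count: int = Field(ge=1)
    effective_power_number: Optional[float] = Field(default=None, gt=0)


class FermenterCase(BaseModel):
    """One scale of the process: broth + vessel + agitator + nominal speed."""

    model_config = ConfigDict(frozen=True)

    label: str
    fluid: Fluid
    vessel: VesselGeometry
    impeller: Impeller
    nominal_speed: float = Field(gt=0, description="N, s⁻¹")


class SimilarityRecord(BaseModel):
    """Geometric-similarity bookkeeping for one scale.

    ``similarity_ratio`` is the operational similarity measure Z_calc/Z₀:
    how much of the as-built liquid height the similarity-derived height
    occupies. It equals 1 at the reference scale and decreases as larger
    vessels are built squatter than strict similarity would demand.
    """

    model_config = ConfigDict(frozen=True)

    scale_label: str
    similarity_ratio: float = Field(gt=0, le=1.05)
    Z_calc: float = Field(gt=0)
    Z_calc_over_T: float = Field(gt=0)
    occupancy_fraction: float = Field(gt=0)

    @model_validator(mode="after")
    def _check(self) -> "SimilarityRecord":
        # similarity_ratio and occupancy share the Z_calc/Z0 definition;
        # they are recorded separately because occupancy may be reported
        # against a different reference height.
        return self


def total_solids_percent(initial_mass: float, moisture_mass: float) -> float:
    """Total solids content of a sample from a gravimetric moisture assay.

    Parameters are masses in grams: the initial sample mass and the mass
    lost as moisture on drying. Returns the solids fraction in percent.
    """
    if initial_mass <= 0:
        raise ValueError(f"initial_mass must be positive, got {initial_mass}")
    if not 0 <= moisture_mass <= initial_mass:
        raise ValueError(
            f"moisture_mass must lie in [0, initial_mass]; got {moisture_mass} "
            f"with initial_mass {initial_mass}"
        )
    return 100.0 * (initial_mass - moisture_mass) / initial_mass


def derive_geometry(
    Z0: float, Z_over_T: float, H_over_T: float, D_over_T: float
) -> dict[str, float]:
    """Derive tank diameter, total height and impeller diameter from ratios.

    Given the actual working height Z₀ and the design ratios, returns a dict
    with keys ``T`` (tank diameter, = Z₀/(Z/T)), ``H`` (= H/T × T) and
    ``D`` (= D/T × T), all in metres.
    """
    for name, v in (("Z0", Z0), ("Z_over_T", Z_over_T),
                    ("H_over_T", H_over_T), ("D_over_T", D_over_T)):
        if v <= 0:
            raise ValueError(f"{name} must be positive, got {v}")
    T = Z0 / Z_over_T
    return {"T": T, "H": H_over_T * T, "D": D_over_T * T}


def calculated_working_height(T: float, target_Z_over_T: float) -> float:
    """Similarity-derived liquid height Z = (Z/T)_target × T, in metres.

    The target aspect ratio is anchored at the reference (smallest) scale,
    so applying it at a larger tank diameter gives the liquid height that
    strict geometric similarity would require there.
    """
    if T <= 0 or target_Z_over_T <= 0:
        raise ValueError("T and target_Z_over_T must be positive")
    return target_Z_over_T * T


def similarity_ratio(Z_calc: float, Z0: float) -> float:
    """Ratio of the similarity-derived height to the as-built height."""
    if Z0 <= 0:
        raise ValueError("Z0 must be positive")
    return Z_calc / Z0


def apply_similarity_ratio(ratio: float, Z0: float) -> float:
    """Project a similarity ratio observed at one scale onto another vessel.

    E.g. the pilot vessel's ratio (≈0.81) applied to the industrial as-built
    height 11.47 m yields a working height of ≈9.29 m, preserving the
    similarity coefficient between adjacent scales.
    """
    if not 0 < ratio <= 1.05:
        raise ValueError(f"ratio must lie in (0, 1.05], got {ratio}")
    if Z0 <= 0:
        raise ValueError("Z0 must be positive")
    return ratio * Z0


def occupancy_percent(Z_calc: float, Z0: float) -> float:
    """Liquid height as a percentage of the reference height.

    Emits a warning when occupancy falls below the customary 80% working
    volume of stirred fermenters; low occupancy wastes installed capacity.
    """
    if Z0 <= 0:
        raise ValueError("Z0 must be positive")
    pct = 100.0 * Z_calc / Z0
    if pct < 100.0 * OCCUPANCY_WARNING_THRESHOLD:
        warnings.warn(
            f"working-height occupancy {pct:.0f}% is below the customary "
            f"{OCCUPANCY_WARNING_THRESHOLD:.0%} of vessel height",
            stacklevel=2,
        )
    return pct


def geometric_scale_factor(V1: float, V2: float) -> float:
    """Linear scale factor (V2/V1)^(1/3) between geometrically similar vessels.

    Multiplies any linear dimension (T, D, Z) of the smaller vessel to give
    the corresponding dimension of the larger one under strict similarity.
    """
    if V1 <= 0 or V2 <= 0:
        raise ValueError("volumes must be positive")
    return (V2 / V1) ** (1.0 / 3.0)
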