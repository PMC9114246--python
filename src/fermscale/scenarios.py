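"""Bundled case study and seeded random scenario generation.

:func:`case_study` loads the packaged three-scale whey-permeate lactic acid
fermentation (laboratory 0.003 m³ working volume, pilot 0.1 m³, industrial
300 m³ vessel holding 207 m³) from the default config file, including the
tall industrial variant whose working height comes from projecting the
pilot similarity ratio. Impeller diameters in these fixtures are derived at
load time by Reynolds inversion from the reported Reynolds numbers; no
diameter is hard-coded.

:func:`random_case` draws physically plausible fluid/vessel/impeller
combinations spanning 10⁻³–10³ m³ for property-based testing. It is a test
instrument only — randomly drawn cases never stand in for the case study.
"""

from __future__ import annotations

import math
from typing import Optional

import numpy as np
from pydantic import BaseModel, ConfigDict, Field

from .core import (
    FermenterCase,
    Fluid,
    Impeller,
    ImpellerType,
    VesselGeometry,
)
from .hydrodynamics import DEFAULT_CORRELATION
from .io import CaseFile, bundled_case_path, load_case_file
from .lca import CML_CATEGORIES, ImpactFactorTable

__all__ = [
    "FixtureSet",
    "ScenarioDistribution",
    "case_study",
    "random_case",
    "random_impact_factors",
]


class FixtureSet(BaseModel):
    """The three bundled cases plus the tall industrial variant.

    ``industrial_tall`` differs from ``industrial`` only in its working
    height (pilot similarity ratio × 11.47 m ≈ 9.29 m instead of the
    strict-similarity 5.98 m); the taller liquid column admits one more
    impeller stage. ``provenance`` maps dotted field names to a note
    saying whether the number is reported source data or derived here,
    and by which oracle.
    """

    model_config = ConfigDict(frozen=True)

    lab: FermenterCase
    pilot: FermenterCase
    industrial: FermenterCase
    industrial_tall: FermenterCase
    provenance: dict[str, str] = Field(default_factory=dict)

    def __iter__(self):
        return iter((self.lab, self.pilot, self.industrial))


_PROVENANCE = {
    "*.fluid.density": "reported (1060 kg/m3 at all scales)",
    "*.fluid.dynamic_viscosity": "reported",
    "*.fluid.kinematic_viscosity": "reported; mu/rho agrees within 2% (independent rounding)",
    "*.impeller.diameter": "derived: Reynolds inversion D = sqrt(Re*mu/(rho*N)) from reported Re at 3.333 1/s",
    "lab.impeller.effective_power_number": "derived: bracketed by reported power draw and dissipation rate (transition regime)",
    "*.vessel.tank_diameter": "derived: Z0 / (Z/T) from reported ratios",
    "*.vessel.calculated_working_height": "derived: target (Z/T) x T",
    "industrial_tall.vessel.calculated_working_height": "derived: pilot similarity ratio (0.81) x 11.47 m",
    "*.nominal_speed": "reported onsite operating speed",
}


def case_study(path: Optional[str] = None) -> FixtureSet:
    """Load the bundled (or a compatible user-supplied) case-study file."""
    cf: CaseFile = load_case_file(path if path is not None else bundled_case_path())
    for needed in ("lab", "pilot", "industrial"):
        if needed not in cf.cases:
            raise ValueError(f"case file lacks required case {needed!r}")
    ind = cf.cases["industrial"]
    alt_Z = cf.alt_working_heights.get("industrial")
    if alt_Z is None:
        alt_Z = ind.vessel.calculated_working_height or ind.vessel.actual_working_height
    tall = ind.model_copy(
        update={
            "label": ind.label + "_tall",
            "vessel": ind.vessel.model_copy(
                update={"calculated_working_height": alt_Z}
            ),
        }
    )
    return FixtureSet(
        lab=cf.cases["lab"],
        pilot=cf.cases["pilot"],
        industrial=ind,
        industrial_tall=tall,
        provenance=dict(_PROVENANCE),
    )


class ScenarioDistribution(BaseModel):
    """Sampling ranges for random fermenter cases.

    Ranges bracket realistic fermentation broths and vessel proportions:
    near-water density, mildly viscous broths, working volumes from bench
    to industrial scale (log-uniform), and conventional impeller and
    aspect ratios.
    """

    model_config = ConfigDict(frozen=True)

    density_range: tuple[float, float] = (950.0, 1200.0)  # kg/m3
    viscosity_range: tuple[float, float] = (0.001, 0.02)  # Pa.s
    working_volume_range: tuple[float, float] = (1e-3, 1e3)  # m3, log-uniform
    d_over_t_range: tuple[float, float] = (0.3, 0.5)
    z_over_t_range: tuple[float, float] = (1.0, 3.0)
    h_over_t_range: tuple[float, float] = (1.5, 3.5)
    speed_range: tuple[float, float] = (0.2, 5.0)  # 1/s
    fill_fraction: float = 0.8  # V_w / V_t


def random_case(
    seed: int | np.random.Generator,
    distribution: ScenarioDistribution = ScenarioDistribution(),
) -> FermenterCase:
    """Draw one internally consistent random fermenter case.

    The vessel is sized as a cylinder at the sampled aspect ratio
    (V_w = π/4·T²·Z₀ with Z₀ = (Z/T)·T), the impeller diameter follows the
    sampled D/T, and the impeller type is uniform over the stock library.
    Identical seeds give identical cases.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    d = distribution
    rho = rng.uniform(*d.density_range)
    mu = rng.uniform(*d.viscosity_range)
    lo, hi = d.working_volume_range
    Vw = float(np.exp(rng.uniform(math.log(lo), math.log(hi))))
    dt = rng.uniform(*d.d_over_t_range)
    zt = rng.uniform(*d.z_over_t_range)
    ht = rng.uniform(*d.h_over_t_range)
    N = rng.uniform(*d.speed_range)
    t = list(ImpellerType)[rng.integers(0, len(ImpellerType))]
    T = (4.0 * Vw / (math.pi * zt)) ** (1.0 / 3.0)
    Z0 = zt * T
    D = dt * T
    count = max(1, math.floor((Z0 - D) / D)) if Z0 > D else 1
    return FermenterCase(
        label=f"random-{rng.bit_generator.state['state']['state'] & 0xFFFF:04x}"
        if hasattr(rng.bit_generator, "state") else "random",
        fluid=Fluid(density=float(rho), dynamic_viscosity=float(mu)),
        vessel=VesselGeometry(
            total_volume=Vw / d.fill_fraction,
            working_volume=Vw,
            tank_diameter=T,
            total_height=ht * T,
            actual_working_height=Z0,
            D_over_T=dt,
            H_over_T=ht,
            Z_over_T=zt,
        ),
        impeller=Impeller(
            type_id=t,
            turbulent_power_number=DEFAULT_CORRELATION.turbulent_po[t],
            diameter=D,
            count=count,
        ),
        nominal_speed=float(N),
    )


def random_impact_factors(seed: int | np.random.Generator) -> ImpactFactorTable:
    """Random non-negative characterization factors for all CML categories.

    Log-uniform over ten decades, reflecting how strongly per-kWh factors
    differ between categories (e.g. ODP vs GWP). Deterministic under seed.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    factors = {
        c: float(10.0 ** rng.uniform(-9, 1)) for c in CML_CATEGORIES
    }
    return ImpactFactorTable(factors=factors)
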