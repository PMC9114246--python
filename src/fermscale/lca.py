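"""Gate-to-gate life cycle impact of fermenter agitation electricity.

Scope is deliberately narrow: the only inventory flow is the electricity
drawn by the agitator motor during one batch, and the functional unit is
1 m³ of substrate processed. Impacts follow the CML 2001 midpoint set
(AP, EP, FAETP, GWP, HTP, ODP, POCP, TETP), each obtained by multiplying
the energy per functional unit by a grid-specific characterization factor
in kg category-equivalent per kWh. Factors are user configuration — they
depend on the electricity mix and database vintage — so every impact is
exactly linear in energy and the turbine ranking is identical in all eight
categories; what the model adds is the energy accounting and the geometry
scenario sweep, not the factors.
"""

from __future__ import annotations

from typing import Optional, Sequence

from pydantic import BaseModel, ConfigDict, Field, model_validator

from .core import FermenterCase, ImpellerType
from .design import DesignCell
from .hydrodynamics import mixing_power, specific_power
from .scaleup import DEFAULT_COUNT_TOLERANCE, feasible_impeller_counts

__all__ = [
    "CML_CATEGORIES",
    "ImpactFactorTable",
    "LcaResult",
    "TurbineComparison",
    "SweepPoint",
    "ScenarioSweep",
    "energy_per_functional_unit",
    "characterize",
    "compare_turbines",
    "scenario_sweep",
    "DEFAULT_BATCH_HOURS",
]

CML_CATEGORIES = ("AP", "EP", "FAETP", "GWP", "HTP", "ODP", "POCP", "TETP")

#: Hours of fermenter operation charged to one batch (one operating day).
DEFAULT_BATCH_HOURS = 20.0


class ImpactFactorTable(BaseModel):
    """Per-category electricity characterization factors, kg-eq per kWh."""

    model_config = ConfigDict(frozen=True)

    factors: dict[str, float]

    @model_validator(mode="after")
    def _check(self) -> "ImpactFactorTable":
        missing = [c for c in CML_CATEGORIES if c not in self.factors]
        if missing:
            raise ValueError(f"missing CML categories: {missing}")
        for c, f in self.factors.items():
            if f < 0:
                raise ValueError(f"factor for {c} must be non-negative, got {f}")
        return self


class LcaResult(BaseModel):
    model_config = ConfigDict(frozen=True)

    energy_kwh_per_m3: float = Field(ge=0)
    impacts: dict[str, float]
    metadata: dict[str, float | int | str] = Field(default_factory=dict)


class TurbineComparison(BaseModel):
    """Per-turbine energies/impacts plus pairwise energy differences.

    ``relative_difference_percent`` maps ``"A_vs_B"`` to 100·(E_A/E_B − 1).
    Because impacts are linear in energy, these percentages apply verbatim
    to every impact category.
    """

    model_config = ConfigDict(frozen=True)

    results: dict[str, LcaResult]
    ranking: tuple[str, ...]  #: labels, lowest energy first
    relative_difference_percent: dict[str, float]


class SweepPoint(BaseModel):
    model_config = ConfigDict(frozen=True)

    Z: float
    H_over_T: float
    tank_diameter: float
    impeller_diameter: float
    feasible_counts: tuple[int, ...] = ()
    feasible: bool = True
    avg_pv_total: Optional[float] = Field(default=None, description="W m⁻³")
    avg_energy_kwh_per_m3: Optional[float] = None
    avg_impacts: Optional[dict[str, float]] = None
    note: str = ""


class ScenarioSweep(BaseModel):
    model_config = ConfigDict(frozen=True)

    impeller_type: ImpellerType
    speed: float
    points: tuple[SweepPoint, ...]


def energy_per_functional_unit(
    P_kw: float, batch_hours: float, substrate_volume: float
) -> float:
    """Electricity per m³ of substrate: E = P·t_batch / V_substrate, kWh m⁻³."""
    for name, v in (
        ("P_kw", P_kw), ("batch_hours", batch_hours),
        ("substrate_volume", substrate_volume),
    ):
        if v <= 0:
            raise ValueError(f"{name} must be positive, got {v}")
    return P_kw * batch_hours / substrate_volume


def characterize(
    energy_kwh_per_m3: float,
    factors: ImpactFactorTable,
    metadata: Optional[dict] = None,
) -> LcaResult:
    """Impact in every CML category: impact_c = E × factor_c."""
    if energy_kwh_per_m3 < 0:
        raise ValueError("energy must be non-negative")
    impacts = {
        c: energy_kwh_per_m3 * factors.factors[c] for c in CML_CATEGORIES
    }
    return LcaResult(
        energy_kwh_per_m3=energy_kwh_per_m3,
        impacts=impacts,
        metadata=metadata or {},
    )


def compare_turbines(
    candidates: Sequence[tuple[str, DesignCell]],
    factors: ImpactFactorTable,
    *,
    batch_hours: float = DEFAULT_BATCH_HOURS,
    substrate_volume: float,
) -> TurbineComparison:
    """Rank turbine/speed candidates by electricity and impacts.

    ``candidates`` are (label, design cell) pairs from one design matrix.
    In a single-flow model the impact ranking necessarily equals the
    energy ranking; the pairwise percentages make the trade-offs explicit
    (a Po-4.4 turbine draws exactly 4.4/5 the power of a Po-5 one at the
    same speed, i.e. 13.6% less).
    """
    if len(candidates) < 2:
        raise ValueError("need at least two candidates to compare")
    results: dict[str, LcaResult] = {}
    for label, cell in candidates:
        E = energy_per_functional_unit(cell.power / 1e3, batch_hours, substrate_volume)
        results[label] = characterize(
            E,
            factors,
            metadata={
                "impeller_type": cell.impeller_type.value,
                "speed_per_s": cell.speed,
                "count": cell.count,
                "power_kW": cell.power / 1e3,
            },
        )
    ranking = tuple(sorted(results, key=lambda k: results[k].energy_kwh_per_m3))
    diffs: dict[str, float] = {}
    labels = [label for label, _ in candidates]
    for i, a in enumerate(labels):
        for b in labels[i + 1:]:
            Ea = results[a].energy_kwh_per_m3
            Eb = results[b].energy_kwh_per_m3
            if Eb > 0:
                diffs[f"{a}_vs_{b}"] = 100.0 * (Ea / Eb - 1.0)
            else:
                diffs[f"{a}_vs_{b}"] = 0.0 if Ea == 0 else float("inf")
    return TurbineComparison(
        results=results, ranking=ranking, relative_difference_percent=diffs
    )


def scenario_sweep(
    case: FermenterCase,
    impeller_type: ImpellerType | str,
    speed: float,
    Z_grid: Sequence[float],
    HT_grid: Optional[Sequence[float]] = None,
    factors: Optional[ImpactFactorTable] = None,
    *,
    power_number: Optional[float] = None,
    count_tolerance: float = DEFAULT_COUNT_TOLERANCE,
    batch_hours: float = DEFAULT_BATCH_HOURS,
    substrate_volume: Optional[float] = None,
    count_policy: str = "mean",
) -> ScenarioSweep:
    """Sweep working height Z and slenderness H/T for one turbine and speed.

    Geometry: the vessel's total height H is held fixed; each H/T point
    rescales the tank diameter as T = H/(H/T) and the impeller diameter
    proportionally (constant D/T), relative to the case's anchored values.
    At each (Z, H/T) the integer stage counts allowed by the height rule
    are enumerated; the specific power (total-volume basis) is aggregated
    over them by ``count_policy`` ("mean", "min" or "max" — mean by
    default, reflecting that either count is an equally probable build).
    Points where no count fits are recorded as gaps, not failures.

    Because power is count-proportional and counts change only at discrete
    Z thresholds, the aggregated P/V is piecewise constant in Z.
    """
    if not Z_grid:
        raise ValueError("Z_grid is empty")
    t = ImpellerType(impeller_type)
    if power_number is None:
        from .hydrodynamics import DEFAULT_CORRELATION

        power_number = DEFAULT_CORRELATION.turbulent_po[t]
    if count_policy not in ("mean", "min", "max"):
        raise ValueError(f"unknown count_policy {count_policy!r}")
    base_HT = case.vessel.H_over_T
    HT_values = list(HT_grid) if HT_grid else [base_HT]
    H = case.vessel.total_height
    T0, D0 = case.vessel.tank_diameter, case.impeller.diameter
    Vt = case.vessel.total_volume
    Vsub = substrate_volume if substrate_volume is not None else case.vessel.working_volume
    rho = case.fluid.density
    points: list[SweepPoint] = []
    for ht in HT_values:
        T = H / ht
        D = D0 * (T / T0)
        for Z in Z_grid:
            try:
                counts = sorted(feasible_impeller_counts(Z, D, count_tolerance))
            except ValueError as exc:
                points.append(
                    SweepPoint(
                        Z=Z, H_over_T=ht, tank_diameter=T, impeller_diameter=D,
                        feasible=False, note=str(exc),
                    )
                )
                continue
            P1 = mixing_power(power_number, speed, D, rho, 1)
            pvs = [specific_power(n * P1, Vt, "total") for n in counts]
            if count_policy == "mean":
                pv = sum(pvs) / len(pvs)
            elif count_policy == "min":
                pv = min(pvs)
            else:
                pv = max(pvs)
            energies = [
                energy_per_functional_unit(n * P1 / 1e3, batch_hours, Vsub)
                for n in counts
            ]
            if count_policy == "mean":
                E = sum(energies) / len(energies)
            elif count_policy == "min":
                E = min(energies)
            else:
                E = max(energies)
            impacts = (
                characterize(E, factors).impacts if factors is not None else None
            )
            points.append(
                SweepPoint(
                    Z=Z, H_over_T=ht, tank_diameter=T, impeller_diameter=D,
                    feasible_counts=tuple(counts), avg_pv_total=pv,
                    avg_energy_kwh_per_m3=E, avg_impacts=impacts,
                )
            )
    return ScenarioSweep(impeller_type=t, speed=speed, points=tuple(points))
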