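"""Impeller-type × speed design matrix, selection criteria and motor sizing.

A candidate grid is built by crossing an impeller library (turbulent power
numbers) with a list of agitation speeds and stage counts, all evaluated in
one vessel with one anchored impeller diameter. Selection then applies, in
order: a specific-power window (2–4 kW per m³ of total vessel volume, the
rule-of-thumb band for industrial fermentations), a shear screen (Kolmogorov
microscale above the largest cell), and finally ranks the survivors by
torque — high torque at low speed means strong bulk circulation per watt.

Motor sizing multiplies the shaft power by a drivetrain correction factor
(default 1.5 for motor, bearing and gearbox losses) and rounds up to the
next standard frame size.
"""

from __future__ import annotations

import warnings
from typing import Optional, Sequence

from pydantic import BaseModel, ConfigDict, Field, model_validator

from .core import FermenterCase, Fluid, ImpellerType
from .hydrodynamics import (
    DEFAULT_CORRELATION,
    FlowRegime,
    PowerCorrelation,
    TorqueMode,
    classify_regime,
    epsilon_t,
    kolmogorov_length,
    mixing_power,
    reynolds,
    shear_safety,
    specific_power,
    torque,
)

__all__ = [
    "DesignCell",
    "DesignMatrix",
    "SelectionCriteria",
    "SelectionReport",
    "MotorSpec",
    "build_design_matrix",
    "filter_by_pv_window",
    "select_impeller",
    "size_motor",
    "DEFAULT_MOTOR_SIZES_KW",
]

#: IEC-like ladder of standard large-motor frame sizes, kW. Fully
#: user-overridable; vendors quote "closest next largest market size".
DEFAULT_MOTOR_SIZES_KW = (
    75.0, 110.0, 160.0, 250.0, 400.0, 630.0, 800.0, 900.0, 1000.0, 1200.0, 1400.0,
)


class DesignCell(BaseModel):
    """One (impeller type, speed, stage count) candidate."""

    model_config = ConfigDict(frozen=True)

    impeller_type: ImpellerType
    power_number: float = Field(gt=0)
    speed: float = Field(gt=0, description="N, s⁻¹")
    rpm: float = Field(gt=0)
    count: int = Field(ge=1)
    reynolds: float = Field(gt=0)
    regime: FlowRegime
    power: float = Field(gt=0, description="W, all stages")
    torque_hp_mode: float = Field(gt=0, description="N·m, vendor formula")
    torque_physical: float = Field(gt=0, description="N·m")
    pv_total: float = Field(gt=0, description="W per m³ of total vessel volume")
    epsilon_t: float = Field(gt=0, description="W kg⁻¹")
    kolmogorov: float = Field(gt=0, description="m")

    def as_row(self) -> dict[str, float | str]:
        """Flat report row in the units design tables are quoted in."""
        return {
            "impeller_type": self.impeller_type.value,
            "power_number": self.power_number,
            "speed_per_s": self.speed,
            "rpm": self.rpm,
            "count": self.count,
            "power_kW": self.power / 1e3,
            "torque_Nm": self.torque_hp_mode,
            "torque_physical_Nm": self.torque_physical,
            "pv_total_kW_per_m3": self.pv_total / 1e3,
            "kolmogorov_um": self.kolmogorov * 1e6,
        }


class DesignMatrix(BaseModel):
    model_config = ConfigDict(frozen=True)

    case_label: str
    impeller_diameter: float = Field(gt=0)
    total_volume: float = Field(gt=0)
    working_volume: float = Field(gt=0)
    cells: tuple[DesignCell, ...]

    def cell(
        self, impeller_type: ImpellerType | str, speed: float, count: int
    ) -> DesignCell:
        t = ImpellerType(impeller_type)
        for c in self.cells:
            if c.impeller_type is t and c.count == count and abs(c.speed - speed) < 1e-9:
                return c
        raise KeyError(f"no cell for ({t.value}, N={speed}, count={count})")


class SelectionCriteria(BaseModel):
    """Filter and ranking knobs for impeller selection.

    ``pv_window_kw`` is in kW per m³ of *total* vessel volume (the basis of
    the rule-of-thumb band); ``window_tolerance`` opens it relatively at
    both ends so that near-miss candidates an engineer would still table
    (e.g. 4.3 against an upper limit of 4) are not discarded outright.
    """

    model_config = ConfigDict(frozen=True)

    pv_window_kw: tuple[float, float] = (2.0, 4.0)
    window_tolerance: float = Field(default=0.1, ge=0)
    require_shear_safe: bool = True

    @model_validator(mode="after")
    def _check(self) -> "SelectionCriteria":
        lo, hi = self.pv_window_kw
        if not lo < hi:
            raise ValueError("pv_window_kw must satisfy min < max")
        return self


class SelectionReport(BaseModel):
    model_config = ConfigDict(frozen=True)

    feasible: bool
    selected: Optional[DesignCell] = None
    candidates: tuple[DesignCell, ...] = ()
    #: selected torque over the next-best candidate's torque
    torque_ratio_runner_up: Optional[float] = None
    #: the other-type candidate whose specific power is closest to the
    #: selected cell's — the natural "same energy intensity" comparator
    closest_pv_competitor: Optional[DesignCell] = None
    torque_ratio_closest_pv: Optional[float] = None
    message: str = ""


class MotorSpec(BaseModel):
    model_config = ConfigDict(frozen=True)

    shaft_power_kw: float = Field(gt=0)
    correction_factor: float = Field(gt=0)
    required_kw: float = Field(gt=0)
    installed_kw: float = Field(gt=0)

    @model_validator(mode="after")
    def _check(self) -> "MotorSpec":
        if self.installed_kw < self.required_kw - 1e-9:
            raise ValueError("installed motor smaller than corrected requirement")
        return self


def build_design_matrix(
    case: FermenterCase,
    speeds: Sequence[float],
    counts: Sequence[int] = (2, 3),
    *,
    library: Optional[dict[ImpellerType, float]] = None,
    correlation: PowerCorrelation = DEFAULT_CORRELATION,
    torque_mode: TorqueMode = TorqueMode.HP_KW,
) -> DesignMatrix:
    """Cross impeller types × speeds × stage counts in one vessel.

    Every cell shares the case's anchored impeller diameter and fluid; only
    Po, N and n vary, so power cells scale exactly as Po ratios at fixed
    speed and as n across counts. Cells outside the turbulent regime are
    kept but flagged with a warning (the turbulent Po is then nominal).
    """
    lib = library if library is not None else correlation.turbulent_po
    if not lib:
        raise ValueError("impeller library is empty")
    if not speeds:
        raise ValueError("speed list is empty")
    D = case.impeller.diameter
    rho = case.fluid.density
    mu = case.fluid.dynamic_viscosity
    Vt = case.vessel.total_volume
    Vw = case.vessel.working_volume
    cells: list[DesignCell] = []
    for t, po in lib.items():
        for N in speeds:
            Re = reynolds(rho, N, D, mu)
            regime = classify_regime(Re)
            if regime is not FlowRegime.TURBULENT:
                warnings.warn(
                    f"{t.value} at N = {N:g} s⁻¹ gives Re = {Re:.3g} "
                    f"({regime.value}); turbulent Po used nominally",
                    stacklevel=2,
                )
            for n in counts:
                P = mixing_power(po, N, D, rho, n)
                eps = epsilon_t(P, rho, Vw)
                cells.append(
                    DesignCell(
                        impeller_type=t,
                        power_number=po,
                        speed=N,
                        rpm=60.0 * N,
                        count=n,
                        reynolds=Re,
                        regime=regime,
                        power=P,
                        torque_hp_mode=torque(P, N, TorqueMode.HP_KW),
                        torque_physical=torque(P, N, TorqueMode.PHYSICAL),
                        pv_total=specific_power(P, Vt, "total"),
                        epsilon_t=eps,
                        kolmogorov=kolmogorov_length(eps, case.fluid.nu),
                    )
                )
    return DesignMatrix(
        case_label=case.label,
        impeller_diameter=D,
        total_volume=Vt,
        working_volume=Vw,
        cells=tuple(cells),
    )


def filter_by_pv_window(
    matrix: DesignMatrix, criteria: SelectionCriteria
) -> tuple[DesignCell, ...]:
    """Cells whose total-volume specific power falls in the window.

    The window is closed and opened by ``window_tolerance`` relatively at
    each end: [lo·(1−τ), hi·(1+τ)] in kW m⁻³. An empty result is allowed.
    """
    lo, hi = criteria.pv_window_kw
    tau = criteria.window_tolerance
    lo_w, hi_w = lo * (1 - tau) * 1e3, hi * (1 + tau) * 1e3
    return tuple(c for c in matrix.cells if lo_w <= c.pv_total <= hi_w)


def select_impeller(
    matrix: DesignMatrix,
    criteria: SelectionCriteria,
    fluid: Fluid,
) -> SelectionReport:
    """Pick the best impeller/speed cell for a broth.

    Window-passing, shear-safe cells are ranked by torque (vendor mode,
    descending), ties broken toward lower power. The report also singles
    out the candidate of a *different* impeller type whose specific power
    is closest to the winner's — the fair "same energy intensity" rival —
    and quotes the torque advantage over it.
    """
    candidates = list(filter_by_pv_window(matrix, criteria))
    if criteria.require_shear_safe:
        if fluid.cell_size_range is None:
            raise ValueError(
                "shear screening requested but fluid has no cell_size_range"
            )
        cell_max_m = fluid.cell_size_range[1] * 1e-6
        candidates = [
            c for c in candidates if shear_safety(c.kolmogorov, cell_max_m)[1]
        ]
    if not candidates:
        return SelectionReport(
            feasible=False, message="no candidate satisfies the selection criteria"
        )
    ranked = sorted(candidates, key=lambda c: (-c.torque_hp_mode, c.power))
    best = ranked[0]
    report: dict = {
        "feasible": True,
        "selected": best,
        "candidates": tuple(ranked),
        "message": (
            f"selected {best.impeller_type.value} at {best.speed:g} s⁻¹ "
            f"({best.count}-stage)"
        ),
    }
    if len(ranked) > 1:
        report["torque_ratio_runner_up"] = (
            best.torque_hp_mode / ranked[1].torque_hp_mode
        )
    rivals = [c for c in ranked if c.impeller_type is not best.impeller_type]
    if rivals:
        rival = min(rivals, key=lambda c: abs(c.pv_total - best.pv_total))
        report["closest_pv_competitor"] = rival
        report["torque_ratio_closest_pv"] = best.torque_hp_mode / rival.torque_hp_mode
    return SelectionReport(**report)


def size_motor(
    P_shaft_kw: float,
    correction: float = 1.5,
    standard_sizes_kw: Sequence[float] = DEFAULT_MOTOR_SIZES_KW,
) -> MotorSpec:
    """Installed motor = smallest standard size ≥ correction × shaft power."""
    if P_shaft_kw <= 0:
        raise ValueError("P_shaft_kw must be positive")
    if correction <= 0:
        raise ValueError("correction must be positive")
    sizes = list(standard_sizes_kw)
    if sizes != sorted(sizes):
        raise ValueError("standard_sizes_kw must be sorted ascending")
    required = correction * P_shaft_kw
    for s in sizes:
        if s >= required - 1e-9:
            return MotorSpec(
                shaft_power_kw=P_shaft_kw,
                correction_factor=correction,
                required_kw=required,
                installed_kw=s,
            )
    raise ValueError(
        f"no standard motor size ≥ {required:g} kW in {sizes}"
    )
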