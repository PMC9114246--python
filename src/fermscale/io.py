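"""Configuration loading and tabular report writing.

Case files are YAML or JSON. A case supplies the fluid, the vessel as
ratios plus the as-built working height (tank diameter, total height and a
default impeller diameter are derived), the impeller, and a nominal speed.
The impeller diameter is resolved in precedence order: an explicit
``diameter``, then a ``reynolds_anchor`` (reported Re at a given speed,
inverted through Re = ρND²/μ), then the geometric D/T ratio.

Unknown keys are rejected so unit mistakes surface as schema errors, not
silently ignored fields.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any, Literal, Optional, Sequence

import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field

from .core import (
    FermenterCase,
    Fluid,
    Impeller,
    ImpellerType,
    VesselGeometry,
    apply_similarity_ratio,
    calculated_working_height,
    derive_geometry,
)
from .hydrodynamics import diameter_from_reynolds
from .lca import ImpactFactorTable

__all__ = [
    "load_cases",
    "load_case_file",
    "load_impact_factors",
    "write_report",
    "bundled_case_path",
    "CaseFile",
]

_DATA_DIR = Path(__file__).parent / "data"


def bundled_case_path() -> Path:
    """Path of the packaged three-scale case-study config."""
    return _DATA_DIR / "cases.yaml"


class _FluidSchema(BaseModel):
    model_config = ConfigDict(extra="forbid")

    density: float
    dynamic_viscosity: float
    kinematic_viscosity: Optional[float] = None
    cell_size_range: Optional[tuple[float, float]] = None


class _ReynoldsAnchor(BaseModel):
    model_config = ConfigDict(extra="forbid")

    reynolds: float = Field(gt=0)
    speed: float = Field(gt=0)


class _VesselSchema(BaseModel):
    model_config = ConfigDict(extra="forbid")

    total_volume: float
    working_volume: float
    actual_working_height: float
    Z_over_T: float
    H_over_T: float
    D_over_T: float
    target_Z_over_T: Optional[float] = None
    alt_similarity_ratio: Optional[float] = None


class _ImpellerSchema(BaseModel):
    model_config = ConfigDict(extra="forbid")

    type: ImpellerType
    turbulent_power_number: float
    count: int = 2
    diameter: Optional[float] = None
    reynolds_anchor: Optional[_ReynoldsAnchor] = None
    effective_power_number: Optional[float] = None


class _CaseSchema(BaseModel):
    model_config = ConfigDict(extra="forbid")

    fluid: _FluidSchema
    vessel: _VesselSchema
    impeller: _ImpellerSchema
    nominal_speed: float


class CaseFile(BaseModel):
    """Parsed case file: validated cases plus per-case extras.

    ``alt_working_heights`` holds, for cases declaring an
    ``alt_similarity_ratio``, the alternative working height obtained by
    projecting that ratio onto the as-built height.
    """

    model_config = ConfigDict(frozen=True)

    cases: dict[str, FermenterCase]
    alt_working_heights: dict[str, float] = Field(default_factory=dict)


def _build_case(label: str, schema: _CaseSchema) -> tuple[FermenterCase, Optional[float]]:
    fl = Fluid(**schema.fluid.model_dump())
    v = schema.vessel
    geo = derive_geometry(v.actual_working_height, v.Z_over_T, v.H_over_T, v.D_over_T)
    Z_calc = (
        calculated_working_height(geo["T"], v.target_Z_over_T)
        if v.target_Z_over_T
        else None
    )
    vessel = VesselGeometry(
        total_volume=v.total_volume,
        working_volume=v.working_volume,
        tank_diameter=geo["T"],
        total_height=geo["H"],
        actual_working_height=v.actual_working_height,
        calculated_working_height=Z_calc,
        D_over_T=v.D_over_T,
        H_over_T=v.H_over_T,
        Z_over_T=v.Z_over_T,
    )
    imp = schema.impeller
    if imp.diameter is not None:
        D = imp.diameter
    elif imp.reynolds_anchor is not None:
        a = imp.reynolds_anchor
        D = diameter_from_reynolds(a.reynolds, fl.density, a.speed, fl.dynamic_viscosity)
    else:
        D = geo["D"]
    impeller = Impeller(
        type_id=imp.type,
        turbulent_power_number=imp.turbulent_power_number,
        diameter=D,
        count=imp.count,
        effective_power_number=imp.effective_power_number,
    )
    case = FermenterCase(
        label=label,
        fluid=fl,
        vessel=vessel,
        impeller=impeller,
        nominal_speed=schema.nominal_speed,
    )
    alt_Z = (
        apply_similarity_ratio(v.alt_similarity_ratio, v.actual_working_height)
        if v.alt_similarity_ratio
        else None
    )
    return case, alt_Z


def _read_structured(path: str | Path) -> dict[str, Any]:
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        return json.loads(text)
    return yaml.safe_load(text)


def load_case_file(path: str | Path) -> CaseFile:
    """Load and validate a YAML/JSON case file."""
    raw = _read_structured(path)
    if not isinstance(raw, dict) or "cases" not in raw:
        raise ValueError(f"{path}: expected a mapping with a top-level 'cases' key")
    cases: dict[str, FermenterCase] = {}
    alts: dict[str, float] = {}
    for label, body in raw["cases"].items():
        schema = _CaseSchema.model_validate(body)
        case, alt_Z = _build_case(label, schema)
        cases[label] = case
        if alt_Z is not None:
            alts[label] = alt_Z
    return CaseFile(cases=cases, alt_working_heights=alts)


def load_cases(path: str | Path | None = None) -> CaseFile:
    """Load a case file, defaulting to the bundled three-scale study."""
    return load_case_file(path if path is not None else bundled_case_path())


def load_impact_factors(path: str | Path) -> ImpactFactorTable:
    """Read electricity characterization factors from CSV, YAML or JSON.

    CSV needs ``category`` and ``factor`` columns; YAML/JSON a flat
    category → factor mapping (kg category-equivalent per kWh).
    """
    path = Path(path)
    if path.suffix.lower() == ".csv":
        df = pd.read_csv(path)
        if not {"category", "factor"} <= set(df.columns):
            raise ValueError(f"{path}: need 'category' and 'factor' columns")
        factors = dict(zip(df["category"], df["factor"].astype(float)))
    else:
        raw = _read_structured(path)
        factors = {str(k): float(v) for k, v in raw.items()}
    return ImpactFactorTable(factors=factors)


def _to_rows(results: Sequence[Any]) -> list[dict[str, Any]]:
    rows = []
    for r in results:
        if hasattr(r, "as_row"):
            rows.append(r.as_row())
        elif isinstance(r, dict):
            rows.append(r)
        elif isinstance(r, BaseModel):
            rows.append(r.model_dump())
        else:
            raise TypeError(f"cannot serialize {type(r).__name__} as a report row")
    return rows


def write_report(
    results: Sequence[Any],
    fmt: Literal["csv", "json"],
    path: str | Path,
) -> Path:
    """Write result rows as CSV (float_format keeps ≥6 significant digits)
    or as a lossless tidy JSON array. An empty result set yields an empty
    table (header-only CSV when column names can be inferred)."""
    path = Path(path)
    rows = _to_rows(results)
    if fmt == "csv":
        df = pd.DataFrame(rows)
        df.to_csv(path, index=False, float_format="%.8g")
    elif fmt == "json":
        path.write_text(json.dumps(rows, indent=2, default=str) + "\n")
    else:
        raise ValueError(f"unknown format {fmt!r}")
    return path
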