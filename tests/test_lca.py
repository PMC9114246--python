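"""Gate-to-gate electricity LCA: linearity, turbine ranking, geometry sweep."""

import pytest
from pydantic import ValidationError

from fermscale import (
    CML_CATEGORIES,
    ImpactFactorTable,
    ImpellerType,
    characterize,
    compare_turbines,
    energy_per_functional_unit,
    scenario_sweep,
)
from fermscale.scenarios import random_impact_factors


@pytest.mark.parametrize(
    "P, t, V, expected",
    [(862.54, 20, 207, 83.3), (100, 10, 500, 2.0), (7.0, 3.0, 21.0, 1.0)],
)
def test_energy_per_functional_unit(P, t, V, expected):
    assert energy_per_functional_unit(P, t, V) == pytest.approx(expected, rel=2e-3)


def test_impact_table_requires_all_categories():
    with pytest.raises(ValidationError, match="missing CML categories"):
        ImpactFactorTable(factors={"GWP": 0.3})
    with pytest.raises(ValidationError):
        ImpactFactorTable(factors={c: -1.0 for c in CML_CATEGORIES})


def test_characterize_is_exactly_linear():
    table = random_impact_factors(7)
    zero = characterize(0.0, table)
    assert all(v == 0.0 for v in zero.impacts.values())
    one = characterize(10.0, table)
    two = characterize(20.0, table)
    for c in CML_CATEGORIES:
        assert one.impacts[c] == pytest.approx(10.0 * table.factors[c], rel=1e-12)
        assert two.impacts[c] == pytest.approx(2 * one.impacts[c], rel=1e-12)


def test_compare_turbines_energy_and_ranking(fx, industrial_matrix):
    table = random_impact_factors(3)
    cells = [
        ("RTB@1.33", industrial_matrix.cell("RTB", 1.33, 2)),
        ("CBT@1.33", industrial_matrix.cell("CBT", 1.33, 2)),
        ("PBT@1.83", industrial_matrix.cell("PBT", 1.83, 2)),
        ("LA315@2.5", industrial_matrix.cell("LA315", 2.5, 2)),
    ]
    cmp = compare_turbines(cells, table, substrate_volume=207.0)
    # Po 5 vs 4.4 at equal speed: exactly 5/4.4 − 1 = 13.6% more electricity
    assert cmp.relative_difference_percent["RTB@1.33_vs_CBT@1.33"] == pytest.approx(
        100 * (5 / 4.4 - 1), rel=1e-9
    )
    # impact ranking equals energy ranking in every category (single flow)
    energies = {k: r.energy_kwh_per_m3 for k, r in cmp.results.items()}
    assert list(cmp.ranking) == sorted(energies, key=energies.get)
    for c in CML_CATEGORIES:
        by_impact = sorted(cmp.results, key=lambda k: cmp.results[k].impacts[c])
        assert by_impact == list(cmp.ranking)
    # GWP ratio equals energy ratio for any factor table (proportionality)
    g = cmp.results
    if table.factors["GWP"] > 0:
        assert (
            g["CBT@1.33"].impacts["GWP"] / g["RTB@1.33"].impacts["GWP"]
        ) == pytest.approx(
            g["CBT@1.33"].energy_kwh_per_m3 / g["RTB@1.33"].energy_kwh_per_m3,
            rel=1e-12,
        )


def test_compare_turbines_tie_and_minimum_candidates(industrial_matrix):
    table = random_impact_factors(5)
    cell = industrial_matrix.cell("RTB", 1.33, 2)
    cmp = compare_turbines(
        [("a", cell), ("b", cell)], table, substrate_volume=207.0
    )
    assert cmp.relative_difference_percent["a_vs_b"] == pytest.approx(0.0, abs=1e-12)
    with pytest.raises(ValueError):
        compare_turbines([("a", cell)], table, substrate_volume=207.0)


def test_scenario_sweep_height_grid(fx):
    sweep = scenario_sweep(
        fx.industrial, ImpellerType.RTB, 1.33, Z_grid=[8.6, 9.1],
        factors=random_impact_factors(11),
    )
    p86, p91 = sweep.points
    assert p86.feasible_counts == (2, 3)
    assert p86.avg_pv_total / 1e3 == pytest.approx(3.59, rel=1e-2)
    # identical feasible sets ⇒ identical averaged P/V (piecewise constant)
    assert p91.avg_pv_total == pytest.approx(p86.avg_pv_total, rel=1e-12)
    assert p86.avg_impacts["GWP"] == pytest.approx(p91.avg_impacts["GWP"], rel=1e-12)


def test_scenario_sweep_single_point_average_is_the_cell(fx):
    sweep = scenario_sweep(fx.industrial, "RTB", 1.33, Z_grid=[5.0])
    (p,) = sweep.points
    assert p.feasible_counts == (1,)
    assert p.avg_pv_total == pytest.approx(
        1 * 5.0 * 1.33**3 * fx.industrial.impeller.diameter**5 * 1060 / 300.0,
        rel=1e-12,
    )


def test_scenario_sweep_slender_vessels_draw_less(fx):
    """Raising H/T at fixed H shrinks T and D, so P/V falls monotonically."""
    sweep = scenario_sweep(
        fx.industrial, "RTB", 1.33, Z_grid=[8.6], HT_grid=[2.5, 3.0, 3.5]
    )
    pts = sorted(sweep.points, key=lambda p: p.H_over_T)
    assert pts[0].tank_diameter > pts[1].tank_diameter > pts[2].tank_diameter
    assert pts[0].impeller_diameter > pts[1].impeller_diameter
    pvs = [p.avg_pv_total for p in pts if p.avg_pv_total is not None]
    assert pvs == sorted(pvs, reverse=True)
    # the baseline H/T keeps the anchored impeller diameter exactly
    base = next(p for p in pts if p.H_over_T == 3.0)
    assert base.impeller_diameter == pytest.approx(
        fx.industrial.impeller.diameter, rel=1e-12
    )


def test_scenario_sweep_records_gaps(fx):
    sweep = scenario_sweep(fx.industrial, "RTB", 1.33, Z_grid=[1.0, 8.6])
    gap, ok = sweep.points
    assert not gap.feasible and gap.note
    assert ok.feasible
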