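"""Design matrix construction, selection criteria and motor sizing."""

import random

import pytest

from fermscale import (
    ImpellerType,
    SelectionCriteria,
    build_design_matrix,
    filter_by_pv_window,
    select_impeller,
    size_motor,
)
from fermscale.design import DesignMatrix
from fermscale.replicate import DESIGN_SPEEDS


def test_matrix_cells_scale_exactly_as_power_numbers(industrial_matrix):
    """At fixed speed and count, P(type)/P(RTB) = Po(type)/5 exactly."""
    rtb = industrial_matrix.cell("RTB", 1.33, 2)
    for t, po in [("CBT", 4.4), ("PBT", 1.64), ("LA310", 0.3),
                  ("LA315", 0.75), ("MP", 0.34)]:
        cell = industrial_matrix.cell(t, 1.33, 2)
        assert cell.power / rtb.power == pytest.approx(po / 5.0, rel=1e-12)


def test_matrix_power_monotone_in_speed_and_po(industrial_matrix):
    for t in ImpellerType:
        powers = [industrial_matrix.cell(t, N, 2).power for N in DESIGN_SPEEDS]
        assert powers == sorted(powers) and len(set(powers)) == len(powers)
    by_po = sorted(
        (industrial_matrix.cell(t, 1.33, 2) for t in ImpellerType),
        key=lambda c: c.power_number,
    )
    powers = [c.power for c in by_po]
    assert powers == sorted(powers)


def test_three_stage_is_exactly_one_and_a_half_two_stage(industrial_matrix):
    for t in ImpellerType:
        c2 = industrial_matrix.cell(t, 1.33, 2)
        c3 = industrial_matrix.cell(t, 1.33, 3)
        assert c3.power / c2.power == pytest.approx(1.5, rel=1e-12)


def test_torque_ordering_matches_power_ordering(industrial_matrix):
    cells = [industrial_matrix.cell(t, 1.33, 2) for t in ImpellerType]
    by_torque = sorted(cells, key=lambda c: c.torque_hp_mode)
    by_power = sorted(cells, key=lambda c: c.power)
    assert [c.impeller_type for c in by_torque] == [c.impeller_type for c in by_power]


def test_matrix_flags_nonturbulent_cells(fx):
    with pytest.warns(UserWarning, match="transition"):
        build_design_matrix(fx.lab, [0.05], (1,))


def test_empty_library_or_speeds_rejected(fx):
    with pytest.raises(ValueError):
        build_design_matrix(fx.industrial, [])
    with pytest.raises(ValueError):
        build_design_matrix(fx.industrial, [1.33], library={})


def test_pv_window_filter(industrial_matrix):
    criteria = SelectionCriteria()
    kept = filter_by_pv_window(industrial_matrix, criteria)
    keys = {(c.impeller_type.value, c.speed, c.count) for c in kept}
    # the rule-of-thumb band retains the five candidates of the case study
    assert {("RTB", 1.33, 2), ("RTB", 1.33, 3), ("CBT", 1.33, 2),
            ("PBT", 1.83, 2), ("LA315", 2.5, 2)} <= keys
    assert ("RTB", 2.5, 2) not in keys  # 19 kW/m³, far above the band
    wide = SelectionCriteria(pv_window_kw=(1e-12, 1e9))
    assert len(filter_by_pv_window(industrial_matrix, wide)) == len(
        industrial_matrix.cells
    )


def test_selection_picks_rushton_at_moderate_speed(fx, industrial_matrix):
    report = select_impeller(industrial_matrix, SelectionCriteria(), fx.industrial.fluid)
    assert report.feasible
    assert report.selected.impeller_type is ImpellerType.RTB
    assert report.selected.speed == pytest.approx(1.33)
    # the same-energy-intensity rival is the LA315 at 2.5 s⁻¹, out-torqued ~1.9×
    assert report.closest_pv_competitor.impeller_type is ImpellerType.LA315
    assert report.torque_ratio_closest_pv == pytest.approx(1.9, rel=2e-2)


def test_selection_invariant_under_cell_order(fx, industrial_matrix):
    shuffled = list(industrial_matrix.cells)
    random.Random(0).shuffle(shuffled)
    m2 = DesignMatrix(
        case_label=industrial_matrix.case_label,
        impeller_diameter=industrial_matrix.impeller_diameter,
        total_volume=industrial_matrix.total_volume,
        working_volume=industrial_matrix.working_volume,
        cells=tuple(shuffled),
    )
    a = select_impeller(industrial_matrix, SelectionCriteria(), fx.industrial.fluid)
    b = select_impeller(m2, SelectionCriteria(), fx.industrial.fluid)
    assert a.selected == b.selected
    assert a.torque_ratio_closest_pv == b.torque_ratio_closest_pv


def test_selection_single_cell_and_no_candidate(fx, industrial_matrix):
    single = DesignMatrix(
        case_label="x",
        impeller_diameter=industrial_matrix.impeller_diameter,
        total_volume=industrial_matrix.total_volume,
        working_volume=industrial_matrix.working_volume,
        cells=(industrial_matrix.cell("RTB", 1.33, 2),),
    )
    rep = select_impeller(single, SelectionCriteria(), fx.industrial.fluid)
    assert rep.selected == industrial_matrix.cell("RTB", 1.33, 2)
    none = select_impeller(
        industrial_matrix,
        SelectionCriteria(pv_window_kw=(500.0, 600.0)),
        fx.industrial.fluid,
    )
    assert not none.feasible and none.selected is None


@pytest.mark.parametrize(
    "P, corr, sizes, expected",
    [
        (596.2, 1.5, [300, 600, 900, 1200, 1500], 900),
        (100, 1.5, [150], 150),
        (400, 1.5, [500, 630, 800], 630),
    ],
)
def test_size_motor(P, corr, sizes, expected):
    spec = size_motor(P, corr, sizes)
    assert spec.installed_kw == expected
    assert spec.required_kw == pytest.approx(corr * P)


def test_size_motor_exhausted_ladder():
    with pytest.raises(ValueError, match="no standard motor size"):
        size_motor(2000.0, 1.5, [300, 600])
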