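"""Reynolds number, power draw, dissipation, microscale, shear and torque."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fermscale import (
    FlowRegime,
    ImpellerType,
    PowerCorrelation,
    TorqueMode,
    classify_regime,
    diameter_from_reynolds,
    epsilon_t,
    evaluate_operating_point,
    kolmogorov_length,
    mixing_power,
    power_number,
    reynolds,
    shear_safety,
    specific_power,
    torque,
)
from fermscale.hydrodynamics import TORQUE_MODE_RATIO

pos = st.floats(1e-3, 1e3, allow_nan=False, allow_infinity=False)


@pytest.mark.parametrize(
    "rho, N, D, mu, expected, rel",
    [
        (1060, 3.333, 0.1814, 0.0057, 2.04e4, 5e-3),
        (1060, 3.333, 2.0295, 0.0057, 2.55e6, 5e-3),
        (1, 1, 1, 1, 1.0, 1e-12),
    ],
)
def test_reynolds_examples(rho, N, D, mu, expected, rel):
    assert reynolds(rho, N, D, mu) == pytest.approx(expected, rel=rel)


def test_reynolds_rejects_nonpositive():
    with pytest.raises(ValueError):
        reynolds(1060, 0.0, 0.1, 0.0057)


@pytest.mark.parametrize(
    "Re, rho, N, mu, expected",
    [
        (2.04e4, 1060, 3.333, 0.0057, 0.1814),
        (2.55319e6, 1060, 3.333, 0.0057, 2.0295),
        (1, 1, 1, 1, 1.0),
    ],
)
def test_diameter_from_reynolds_examples(Re, rho, N, mu, expected):
    assert diameter_from_reynolds(Re, rho, N, mu) == pytest.approx(expected, rel=5e-4)


@given(Re=st.floats(1, 1e8), rho=pos, N=pos, mu=st.floats(1e-4, 1))
def test_reynolds_inversion_round_trip(Re, rho, N, mu):
    """diameter_from_reynolds is the exact inverse of reynolds."""
    D = diameter_from_reynolds(Re, rho, N, mu)
    assert reynolds(rho, N, D, mu) == pytest.approx(Re, rel=1e-12)


@pytest.mark.parametrize(
    "Re, regime",
    [
        (2.55e6, FlowRegime.TURBULENT),
        (1810, FlowRegime.TRANSITION),
        (5, FlowRegime.LAMINAR),
        (1e4, FlowRegime.TRANSITION),  # boundary: turbulent requires Re > 1e4
    ],
)
def test_classify_regime(Re, regime):
    assert classify_regime(Re) is regime


def test_power_number_branches():
    assert power_number(ImpellerType.RTB, 2.55e6) == 5.0
    assert power_number(ImpellerType.PBT, 1e5) == 1.64
    # laminar: Po = K_L/Re with the default K_L = 64 for RTB
    assert power_number(ImpellerType.RTB, 8.0) == pytest.approx(64 / 8.0)
    with pytest.warns(UserWarning, match="transition"):
        assert power_number(ImpellerType.RTB, 1810) == 5.0


def test_power_number_effective_transition_and_missing_type():
    corr = PowerCorrelation(
        transition_policy="effective",
        effective_transition_po={ImpellerType.RTB: 4.55},
    )
    assert power_number(ImpellerType.RTB, 1810, corr) == 4.55
    empty = PowerCorrelation(turbulent_po={}, laminar_kl={})
    with pytest.raises(KeyError):
        power_number(ImpellerType.RTB, 1e5, empty)


@pytest.mark.parametrize(
    "Po, N, D, rho, n, expected, rel",
    [
        (5, 3.333, 0.1814, 1060, 2, 77.1, 5e-3),
        (5, 1.33, 2.0295, 1060, 2, 858.7e3, 5e-3),
    ],
)
def test_mixing_power_examples(Po, N, D, rho, n, expected, rel):
    assert mixing_power(Po, N, D, rho, n) == pytest.approx(expected, rel=rel)


@given(Po=pos, N=pos, D=pos, rho=pos, k=st.floats(0.1, 10))
def test_mixing_power_homogeneity(Po, N, D, rho, k):
    """P scales as N³ and as D⁵, and is linear in the stage count."""
    base = mixing_power(Po, N, D, rho, 1)
    assert mixing_power(Po, k * N, D, rho, 1) == pytest.approx(k**3 * base, rel=1e-9)
    assert mixing_power(Po, N, k * D, rho, 1) == pytest.approx(k**5 * base, rel=1e-9)
    assert mixing_power(Po, N, D, rho, 2) == pytest.approx(2 * base, rel=1e-12)


def test_specific_power_bases():
    assert specific_power(9425.137, 207, "working") == pytest.approx(45.53, rel=1e-3)
    assert specific_power(862.54e3, 300, "total") == pytest.approx(2875.0, rel=1e-3)
    assert specific_power(0.0, 1.0, "working") == 0.0
    with pytest.raises(ValueError):
        specific_power(1.0, 1.0, "per-batch")


@pytest.mark.parametrize(
    "P, rho, Vw, expected",
    [(77.006, 1060, 0.1, 0.7265), (0.257, 1060, 0.003, 0.0808), (1060, 1060, 1, 1.0)],
)
def test_epsilon_examples(P, rho, Vw, expected):
    assert epsilon_t(P, rho, Vw) == pytest.approx(expected, rel=1e-3)


@pytest.mark.parametrize(
    "eps, nu, expected_um",
    [(0.0430, 5.37e-6, 245.1), (0.7265, 5.37e-6, 120.9)],
)
def test_kolmogorov_examples(eps, nu, expected_um):
    assert kolmogorov_length(eps, nu) * 1e6 == pytest.approx(expected_um, rel=2e-3)


def test_kolmogorov_unit_ratio_case():
    nu = 3.7e-6
    assert kolmogorov_length(nu**3, nu) == pytest.approx(1.0, rel=1e-12)


@given(eps=st.floats(1e-4, 10), nu=st.floats(1e-7, 1e-4), k=st.floats(1.01, 10))
def test_kolmogorov_monotonicity(eps, nu, k):
    """λ_k shrinks with dissipation and grows with viscosity."""
    lam = kolmogorov_length(eps, nu)
    assert kolmogorov_length(k * eps, nu) < lam
    assert kolmogorov_length(eps, k * nu) > lam


def test_shear_safety_margins():
    margin, safe = shear_safety(245.12e-6, 1.9e-6)
    assert margin == pytest.approx(129, rel=5e-3)
    assert safe
    assert shear_safety(1.9e-6, 1.9e-6) == (pytest.approx(1.0), False)
    assert shear_safety(0.95e-6, 1.9e-6) == (pytest.approx(0.5), False)


def test_torque_examples():
    # vendor-mode values from the industrial design sheet (quoted at the
    # rounded 80 rpm, i.e. N = 80/60 s⁻¹)
    assert torque(862.54e3, 80 / 60, TorqueMode.HP_KW) == pytest.approx(76775, rel=1e-4)
    assert torque(853.49e3, 2.5, "hp_kw") == pytest.approx(40517, rel=1e-4)
    assert torque(2 * math.pi, 1.0) == pytest.approx(1.0, rel=1e-12)
    with pytest.raises(ValueError):
        torque(100.0, 0.0)


@given(P=st.floats(1e-3, 1e7), N=st.floats(1e-2, 10))
def test_torque_mode_ratio_is_constant(P, N):
    """Vendor-formula torque is exactly 0.74570× the physical P/(2πN)."""
    ratio = torque(P, N, TorqueMode.HP_KW) / torque(P, N, TorqueMode.PHYSICAL)
    assert ratio == pytest.approx(TORQUE_MODE_RATIO, rel=1e-12)
    assert abs(ratio - 0.74570) < 1e-4


def test_operating_point_chain_consistency(fx):
    """The assembled operating point agrees with the individual operations."""
    op = evaluate_operating_point(fx.pilot)
    assert op.rpm == pytest.approx(60 * op.speed, rel=1e-12)
    assert op.regime is FlowRegime.TURBULENT
    assert op.power == pytest.approx(
        mixing_power(5.0, op.speed, fx.pilot.impeller.diameter, 1060, 2), rel=1e-12
    )
    assert op.epsilon_t == pytest.approx(op.power / (1060 * 0.1), rel=1e-12)
    assert op.torque_hp_mode / op.torque_physical == pytest.approx(
        TORQUE_MODE_RATIO, rel=1e-12
    )


def test_lab_case_uses_effective_transition_power_number(fx):
    op = evaluate_operating_point(fx.lab)
    assert op.regime is FlowRegime.TRANSITION
    assert op.power_number == fx.lab.impeller.effective_power_number
    assert op.power_number < fx.lab.impeller.turbulent_power_number
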