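"""Closed-form solution, oscillation characteristics and branch corrections."""

import math

import numpy as np
import pytest

from twosho.closedform import (
    OscillationCharacteristics,
    convert_phase_convention,
    evaluate_waveform,
    feasibility_check,
    large_k2_limit_signs,
    phase_corrections,
    solve_closed_form,
    wrap_phase,
)
from twosho.params import (
    InitialState,
    build_linear_system,
    derive_dependent_parameters,
    fixed_point,
)

from conftest import random_oscillator

# frozen from the independent oracle: numerical ODE integration followed by a
# linear least-squares sinusoid fit (a sin + b cos + c) of each species
ORACLE_ALPHA = (2.995649750, 5.668480717)
ORACLE_PHI_SIN = (0.0, 2.127599422)
ORACLE_OMEGA = (5.000000000, 5.677749361)


def test_worked_example_characteristics(nominal):
    p, x0 = nominal
    oc = solve_closed_form(p, x0)
    assert oc.theta == pytest.approx(6.281074749, abs=1e-8)
    assert oc.alpha == pytest.approx(ORACLE_ALPHA, abs=1e-8)
    assert oc.omega == pytest.approx(ORACLE_OMEGA, abs=1e-8)
    oc_sin = convert_phase_convention(oc, "sin")
    assert oc_sin.phi == pytest.approx(ORACLE_PHI_SIN, abs=1e-8)


def test_starting_at_the_fixed_point_gives_constant_solution():
    p = derive_dependent_parameters(1.0, 2.0, 3.0, k4=4.0, k6=10.0)
    w = fixed_point(build_linear_system(p))
    oc = solve_closed_form(p, InitialState(*w))
    assert oc.alpha == pytest.approx((0.0, 0.0), abs=1e-12)
    assert oc.phi == (0.0, 0.0)  # degenerate phases default to zero


def test_closed_form_satisfies_the_ode():
    """Central-difference derivative of the waveform matches A x + u.

    The truncation error of the central difference is (theta*dt)^2/6 of the
    derivative scale; at 20000 points per period this is ~1.6e-9 relative,
    so an 1e-7 relative bound cleanly separates a correct solution from a
    wrong one.
    """
    rng = np.random.default_rng(17)
    for _ in range(25):
        p, x0 = random_oscillator(rng)
        sys = build_linear_system(p)
        oc = solve_closed_form(p, x0)
        period = 2 * math.pi / oc.theta
        t = np.linspace(0, 2 * period, 40001)
        dt = t[1] - t[0]
        x = evaluate_waveform(oc, t).stack()
        dx = (x[:, 2:] - x[:, :-2]) / (2 * dt)
        rhs = sys.A @ x[:, 1:-1] + sys.u[:, None]
        scale = max(1.0, float(np.max(np.abs(rhs))))
        assert np.max(np.abs(dx - rhs)) < 1e-7 * scale


def test_waveform_reproduces_initial_state():
    rng = np.random.default_rng(23)
    for _ in range(25):
        p, x0 = random_oscillator(rng)
        oc = solve_closed_form(p, x0)
        np.testing.assert_allclose(oc.x0(), x0.as_array(), rtol=1e-9, atol=1e-9)


def test_waveform_periodicity_and_mean(nominal):
    p, x0 = nominal
    oc = solve_closed_form(p, x0)
    period = 2 * math.pi / oc.theta
    t = np.linspace(0.0, period, 257)[:-1]  # one exact period, endpoint excluded
    a = evaluate_waveform(oc, t)
    b = evaluate_waveform(oc, t + period)
    np.testing.assert_allclose(a.stack(), b.stack(), rtol=0, atol=1e-9)
    assert np.mean(a.x1) == pytest.approx(oc.omega[0], abs=1e-9)
    assert np.mean(a.x2) == pytest.approx(oc.omega[1], abs=1e-9)


def test_phase_convention_round_trip(nominal):
    p, x0 = nominal
    oc = solve_closed_form(p, x0)
    oc_sin = convert_phase_convention(oc, "sin")
    assert oc_sin.phi[0] == pytest.approx(wrap_phase(oc.phi[0] + math.pi / 2))
    back = convert_phase_convention(oc_sin, "cos")
    assert back.phi == pytest.approx(oc.phi, abs=1e-12)
    t = np.linspace(0, 5, 101)
    np.testing.assert_allclose(
        evaluate_waveform(oc, t).stack(), evaluate_waveform(oc_sin, t).stack(),
        rtol=0, atol=1e-12,
    )
    with pytest.raises(ValueError):
        convert_phase_convention(oc, "tan")


def test_phase_corrections_match_atan2_branches():
    """pi_n = pi exactly when the atan2 phase lies in the upper half plane."""
    rng = np.random.default_rng(29)
    checked = 0
    for _ in range(200):
        p, x0 = random_oscillator(rng)
        oc = solve_closed_form(p, x0)
        pc = phase_corrections(p, x0, oc.theta)
        sys = build_linear_system(p)
        hp0 = sys.A @ x0.as_array() + sys.u
        # cond1 and cond2 reduce to h1'(0)/theta and -h2'(0)/theta
        assert pc.cond1 == pytest.approx(hp0[0] / oc.theta, rel=1e-6, abs=1e-9)
        assert pc.cond2 == pytest.approx(-hp0[1] / oc.theta, rel=1e-6, abs=1e-9)
        for n, pi_n in ((1, pc.pi1), (2, pc.pi2)):
            phi = oc.phi[n - 1]
            if oc.alpha[n - 1] < 1e-9 or abs(math.sin(phi)) < 1e-9:
                continue  # degenerate or boundary case: branch is arbitrary
            assert (pi_n == math.pi) == (math.sin(phi) > 0)
            checked += 1
    assert checked > 100


def test_phase_corrections_limits_and_T(nominal):
    p, x0 = nominal
    # huge k6 makes cond2 negative, removing the pi correction of species 2
    p_big = p.replace(k6=1e9)
    pc = phase_corrections(p_big, x0, p_big.theta)
    assert pc.cond2 < 0 and pc.pi2 == 0.0
    # T vanishes only when k4 = k6 and both initial concentrations are zero
    p_eq = derive_dependent_parameters(0.0, 1.0, 1.0, k4=3.0, k6=3.0)
    pc0 = phase_corrections(p_eq, InitialState(0.0, 0.0), 1.0)
    assert pc0.T == 0.0
    with pytest.raises(ZeroDivisionError):
        phase_corrections(p, x0, 0.0)


def test_feasibility_check_boundary_and_violation():
    oc = OscillationCharacteristics(
        theta=1.0, alpha=(3.0, 5.67), phi=(0.0, 0.0), omega=(5.0, 5.68)
    )
    assert feasibility_check(oc)
    grazing = OscillationCharacteristics(
        theta=1.0, alpha=(2.0, 2.0), phi=(0.0, 0.0), omega=(2.0, 2.0)
    )
    assert feasibility_check(grazing)  # equality counts as feasible
    bad = OscillationCharacteristics(
        theta=1.0, alpha=(2.1, 1.0), phi=(0.0, 0.0), omega=(2.0, 2.0)
    )
    assert not feasibility_check(bad)
    with pytest.raises(ValueError):
        feasibility_check(oc, tol=-1.0)


def test_large_k2_limit_signs():
    x0 = InitialState(1.0, 2.0)
    # equal boundary rates: T > 0 dominates and both limits are negative
    assert large_k2_limit_signs(3.0, 3.0, 1.0, x0) == (-1.0, -1.0)
    # T >= |k6 - k4| algebraically, so the first sign is never positive when
    # the initial concentrations are nonzero, however large k6 is
    s1, s2 = large_k2_limit_signs(0.0, 100.0, 1.0, x0)
    assert s1 == -1.0 and s2 == -1.0
    # with zero initial concentrations the bracket degenerates to sign(0)
    s1, s2 = large_k2_limit_signs(0.0, 100.0, 1.0, InitialState(0.0, 0.0))
    assert s1 == 0.0 and s2 == -1.0
    with pytest.raises(ValueError):
        large_k2_limit_signs(1.0, 1.0, 0.0, x0)


def test_large_k2_limit_signs_match_closed_form_at_huge_k2():
    x0 = InitialState(1.0, 2.0)
    rng = np.random.default_rng(31)
    for _ in range(20):
        k4, k6 = rng.uniform(0, 50, size=2)
        theta = rng.uniform(0.5, 5.0)
        signs = large_k2_limit_signs(k4, k6, theta, x0)
        k2 = 1e6
        p = derive_dependent_parameters(1.0, k2, theta**2 / k2, k4=k4, k6=k6)
        oc = solve_closed_form(p, x0)
        for n in (0, 1):
            margin = oc.omega[n] - oc.alpha[n]
            if abs(margin) > 1e-3:  # skip numerically indeterminate boundaries
                assert np.sign(margin) == signs[n]


def test_k1_is_irrelevant_to_oscillation_characteristics():
    base = None
    for k1 in (0.0, 1.0, 10.0):
        p = derive_dependent_parameters(k1, 3.91, 10.09, k4=41.75, k6=92.2)
        oc = solve_closed_form(p, InitialState(5.0, 10.49))
        vals = (oc.theta, *oc.alpha, *oc.phi, *oc.omega)
        if base is None:
            base = vals
        else:
            assert vals == pytest.approx(base, rel=1e-12)


def test_species_lock_into_antiphase_as_k2_grows():
    """For large k2 (kd = theta^2/k2 -> 0) the sum x1 + x2 is nearly
    conserved, so the oscillating parts of the two species cancel: with
    non-negative amplitudes the canonical phases approach a gap of exactly
    pi (the same motion described with signed amplitudes would have equal
    phases)."""
    x0 = InitialState(4.0, 6.0)
    gaps = []
    for k2 in (10.0, 1e3, 1e6):
        p = derive_dependent_parameters(1.0, k2, 4.0 / k2, k4=3.0, k6=7.0)
        oc = solve_closed_form(p, x0)
        gaps.append(abs(wrap_phase(oc.phi[0] - oc.phi[1] + math.pi)))
    assert gaps[2] < gaps[1] < gaps[0]
    assert gaps[2] < 1e-2
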