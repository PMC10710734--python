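"""The oscillator design algorithm: search-space reduction, losses, fitting."""

import math

import numpy as np
import pytest

from twosho.closedform import convert_phase_convention, solve_closed_form
from twosho.design import (
    DesignTarget,
    LossConfig,
    SearchPoint,
    design_errors,
    loss,
    parameterize_oscillator,
    reduce_search_space,
    relaxed_loss,
    run_study_grid,
    target_waveform,
)
from twosho.params import InitialState


def test_reduce_search_space_pins_frequency():
    target = DesignTarget(theta_star=6.28, alpha_star=1.0, phi_star=0.0, omega_star=1.0)
    p = reduce_search_space(target, SearchPoint(k2=3.91, k4=1.0, k6=2.0, x1_0=1.0, x2_0=1.0))
    assert p.k1 == 1.0
    assert p.kd == pytest.approx(6.28**2 / 3.91, rel=1e-15)  # ~ 10.09
    assert p.theta == pytest.approx(6.28, rel=1e-14)
    simple = reduce_search_space(
        DesignTarget(1.0, 1.0, 0.0, 1.0), SearchPoint(1.0, 0.0, 0.0, 1.0, 1.0)
    )
    assert simple.kd == 1.0
    rng = np.random.default_rng(3)
    for _ in range(20):
        ts = rng.uniform(0.1, 50)
        pt = SearchPoint(rng.uniform(0.1, 100), 1.0, 2.0, 1.0, 1.0)
        tgt = DesignTarget(ts, 1.0, 0.0, 1.0)
        assert reduce_search_space(tgt, pt).theta == pytest.approx(ts, rel=1e-14)


def test_target_validation():
    with pytest.raises(ValueError):
        DesignTarget(0.0, 1.0, 0.0, 1.0)
    with pytest.raises(ValueError):
        DesignTarget(1.0, -1.0, 0.0, 1.0)
    # phases are canonicalized into (-pi, pi]
    assert DesignTarget(1.0, 1.0, 3 * math.pi, 1.0).phi_star == pytest.approx(math.pi)


def _self_consistent_target(point: SearchPoint, theta_star: float) -> DesignTarget:
    """Target whose waveform is exactly species 1 of the lifted point."""
    probe = DesignTarget(theta_star, 1.0, 0.0, 0.0)
    p = reduce_search_space(probe, point)
    oc = convert_phase_convention(
        solve_closed_form(p, InitialState(point.x1_0, point.x2_0)), "sin"
    )
    return DesignTarget(theta_star, oc.alpha[0], oc.phi[0], oc.omega[0])


def test_loss_definition_and_brute_force():
    point = SearchPoint(k2=2.0, k4=3.0, k6=10.0, x1_0=2.0, x2_0=3.0)
    target = _self_consistent_target(point, theta_star=1.5)
    grid = LossConfig().time_grid(target.theta_star)
    # candidate matching the target exactly has zero loss
    assert loss(point, target, 1, grid) == pytest.approx(0.0, abs=1e-18)
    # constant offset c at M grid points contributes M*c^2
    shifted = DesignTarget(
        target.theta_star, target.alpha_star, target.phi_star, target.omega_star + 0.7
    )
    assert loss(point, shifted, 1, grid) == pytest.approx(len(grid) * 0.7**2, rel=1e-12)
    # generic candidate: agrees with an independent re-summation over the grid
    other = SearchPoint(k2=1.0, k4=1.0, k6=5.0, x1_0=1.0, x2_0=4.0)
    p = reduce_search_space(target, other)
    oc = solve_closed_form(p, InitialState(other.x1_0, other.x2_0))
    x1 = oc.alpha[0] * np.cos(oc.theta * grid + oc.phi[0]) + oc.omega[0]
    brute = sum((xs - xv) ** 2 for xs, xv in zip(target_waveform(target, grid), x1))
    assert loss(other, target, 1, grid) == pytest.approx(brute, rel=1e-12)


def test_relaxed_loss_penalty():
    cfg = LossConfig()
    target = DesignTarget(1.0, 1.0, 0.0, 1.0)
    grid = cfg.time_grid(target.theta_star)
    # everywhere non-negative trajectories: relaxed loss equals the plain loss
    # (this point sits at its own fixed point (2, 2): constant positive state)
    nonneg = SearchPoint(k2=1.0, k4=4.0, k6=6.0, x1_0=2.0, x2_0=2.0)
    assert relaxed_loss(nonneg, target, 1, grid, cfg) == pytest.approx(
        loss(nonneg, target, 1, grid)
    )
    # a violating candidate: the penalty equals the independently computed
    # weighted sum of squared negative excursions, and dominates
    from twosho.closedform import evaluate_waveform

    bad = SearchPoint(k2=1.0, k4=20.0, k6=1.0, x1_0=0.1, x2_0=20.0)
    p = reduce_search_space(target, bad)
    traj = evaluate_waveform(solve_closed_form(p, InitialState(bad.x1_0, bad.x2_0)), grid)
    pen = sum(np.sum((cfg.w * np.minimum(x, 0.0)) ** 2) for x in (traj.x1, traj.x2))
    assert pen > 0
    assert relaxed_loss(bad, target, 1, grid, cfg) == pytest.approx(
        loss(bad, target, 1, grid) + pen, rel=1e-12
    )
    # relaxed >= plain always
    rng = np.random.default_rng(7)
    for _ in range(30):
        pt = SearchPoint(*rng.uniform(0.1, 30, size=5))
        assert relaxed_loss(pt, target, 2, grid, cfg) >= loss(pt, target, 2, grid) - 1e-12


def test_design_errors_definition():
    target = DesignTarget(1.0, 2.0, 0.5, 2.0)
    assert design_errors((2.0, 0.5), target) == pytest.approx((0.0, 0.0))
    amp, _ = design_errors((0.0, 0.5), target)
    assert amp == -1.0  # species pinned at a constant: no oscillation at all
    _, ph = design_errors((2.0, 0.5 + 2 * math.pi), target)
    assert ph == pytest.approx(0.0, abs=1e-12)
    _, ph = design_errors((2.0, 0.5 + math.pi), target)
    assert ph == pytest.approx(0.5)


def test_parameterize_easy_target_is_exact():
    target = DesignTarget(theta_star=1.0, alpha_star=1.0, phi_star=0.0, omega_star=1.0)
    res = parameterize_oscillator(target, LossConfig(seed=2, n_restarts=6))
    assert abs(res.amplitude_design_error) < 0.01
    assert abs(res.phase_design_error) < 0.01
    assert res.ocs.theta == 1.0  # exact by construction
    assert res.params.k1 == 1.0
    assert res.feasible
    assert res.chosen_species == (1 if res.losses[0] <= res.losses[1] else 2)


def test_parameterize_is_deterministic():
    target = DesignTarget(2.0, 3.0, math.pi / 2, 3.0)
    cfg = LossConfig(seed=5, n_restarts=3)
    a = parameterize_oscillator(target, cfg)
    b = parameterize_oscillator(target, cfg)
    assert a.to_dict() == b.to_dict()


def test_species_choice_never_worse_than_s1_only():
    targets = [DesignTarget(0.5, 2.0, math.pi / 2, 2.0), DesignTarget(5.0, 0.5, 0.0, 0.5)]
    cfg = LossConfig(seed=9, n_restarts=4)
    free = run_study_grid(targets, cfg)
    s1 = run_study_grid(targets, cfg, s1_only=True)
    assert (s1["chosen_species"] == "a").all()
    assert (
        free["selected_relaxed_loss"].to_numpy()
        <= s1["selected_relaxed_loss"].to_numpy() + 1e-12
    ).all()


def test_study_grid_schema():
    cfg = LossConfig(seed=1, n_restarts=3)
    table = run_study_grid([DesignTarget(1.0, 1.0, 0.0, 1.0)], cfg)
    assert len(table) == 1
    for col in ("theta_star", "alpha_star", "phi_star", "chosen_species",
                "amplitude_design_error", "phase_design_error",
                "feasibility_design_error", "k2", "k4", "k6"):
        assert col in table.columns
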