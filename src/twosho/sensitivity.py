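"""Parameter sensitivity of the oscillator: analytic and Monte-Carlo.

Two complementary views of robustness to kinetic-constant variability:

* The frequency theta = sqrt(k2*(k5-k3)) admits exact relative
  sensitivities S_k = (dtheta/dk)(k/theta): 1/2 for k2,
  -k3/(2(k5-k3)) for k3 and k5/(2(k5-k3)) for k5, zero for every other
  parameter.  Their k3/k5 pair always sums to 1/2.

* The remaining characteristics are complicated functions of the
  parameters, so they are studied by Monte Carlo: each parameter that an
  experimentalist would have to realize (k1, k2, k4, k5, k6 and both
  initial concentrations) is drawn independently from a normal
  distribution centered on its nominal value with standard deviation
  cv * nominal, truncated at zero by rejection.  k3 is recomputed as
  k1 + k2 for every draw (the network construction enforces it), and
  kd = k5 - k3 may come out non-positive, in which case the draw cannot
  oscillate.  A draw is *feasible* when kd > 0 and the resulting
  oscillation keeps both concentrations non-negative (omega_n >= alpha_n).

The chance of at least one feasible realization in m independent attempts
with per-try feasibility f is p(m, f) = 1 - (1-f)^m.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .closedform import feasibility_check, solve_closed_form, wrap_phase
from .params import InitialState, KineticParameters, frequency

__all__ = [
    "SensitivityStudyConfig",
    "SensitivityStudyResult",
    "analytic_frequency_sensitivity",
    "numeric_frequency_sensitivity",
    "sample_parameters",
    "feasibility_study",
    "success_probability",
]

#: parameters drawn in the Monte-Carlo study (k3 is recomputed per draw)
SAMPLED = ("k1", "k2", "k4", "k5", "k6", "x1_0", "x2_0")


def analytic_frequency_sensitivity(p: KineticParameters, which: str) -> float:
    """Relative sensitivity S_k^theta = (dtheta/dk)(k/theta) of the frequency.

    Only k2, k3 and k5 enter theta = sqrt(k2*(k5-k3)); the sensitivity is
    zero for every other constant and for the initial concentrations.
    """
    if which == "k2":
        return 0.5
    if which in ("k3", "k5"):
        gap = p.k5 - p.k3
        if gap <= 0:
            raise ZeroDivisionError("k5 = k3: frequency sensitivity is singular")
        return -p.k3 / (2 * gap) if which == "k3" else p.k5 / (2 * gap)
    if which in ("k1", "k4", "k6", "kd", "x1_0", "x2_0"):
        return 0.0
    raise KeyError(f"unknown parameter {which!r}")


def numeric_frequency_sensitivity(
    p: KineticParameters, which: str, step: float = 1e-6
) -> float:
    """Central-difference estimate of the relative frequency sensitivity.

    k2, k3 and k5 are perturbed as independent arguments of
    theta(k2, k3, k5) = sqrt(k2*(k5-k3)); all other parameters do not enter
    the frequency at all.
    """
    if step <= 0:
        raise ValueError("step must be positive")

    def theta_of(k2: float, k3: float, k5: float) -> float:
        return frequency(k2, k5 - k3)

    base = {"k2": p.k2, "k3": p.k3, "k5": p.k5}
    if which not in base:
        return 0.0
    k = base[which]
    h = step * max(1.0, abs(k))
    hi, lo = dict(base), dict(base)
    hi[which] = k + h
    lo[which] = k - h
    d = (theta_of(**hi) - theta_of(**lo)) / (2 * h)
    return d * k / theta_of(**base)


def success_probability(m: int, f: float) -> float:
    """p(m, f) = 1 - (1 - f)^m: chance of a feasible oscillator in m tries."""
    if m < 1 or int(m) != m:
        raise ValueError("m must be a positive integer")
    if not 0.0 <= f <= 1.0:
        raise ValueError("f must lie in [0, 1]")
    return 1.0 - (1.0 - f) ** m


@dataclass(frozen=True)
class SensitivityStudyConfig:
    """Monte-Carlo study setup around a nominal oscillator."""

    nominal_params: KineticParameters
    nominal_x0: InitialState
    cv_grid: tuple[float, ...] = (0.01, 0.05, 0.1, 0.2)
    n_samples: int = 400
    seed: int = 0
    feasibility_tol: float = 1e-9

    def __post_init__(self) -> None:
        if any(cv < 0 for cv in self.cv_grid):
            raise ValueError("coefficients of variation must be non-negative")
        if self.n_samples < 1:
            raise ValueError("n_samples must be at least 1")


@dataclass(frozen=True)
class SensitivityStudyResult:
    """Feasibility fractions and OC-deviation statistics per noise level.

    ``table`` has one row per cv with the feasibility fraction, its
    binomial standard error, mean absolute fractional deviations of theta,
    alpha_n and omega_n among feasible draws, and mean absolute phase
    deviations in radians (phases are not normalized because the nominal
    phase may be zero).
    """

    config: SensitivityStudyConfig = field(repr=False)
    table: pd.DataFrame
    analytic_sensitivities: dict[str, float]


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float) -> float:
    """One non-negative draw by rejection (clipping would pile mass at 0)."""
    if sd == 0:
        return mean
    while True:
        v = rng.normal(mean, sd)
        if v >= 0:
            return v


def sample_parameters(
    cfg: SensitivityStudyConfig, cv: float, rng: np.random.Generator | None = None
) -> list[tuple[dict, float]]:
    """Draw ``cfg.n_samples`` perturbed parameter sets at one noise level.

    Returns raw draws as dicts over SAMPLED plus the implied kd = k5 - k3;
    kd <= 0 marks a draw that cannot oscillate and is kept so that callers
    can count it as infeasible.
    """
    if cv < 0:
        raise ValueError("cv must be non-negative")
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    nominal = {
        "k1": cfg.nominal_params.k1,
        "k2": cfg.nominal_params.k2,
        "k4": cfg.nominal_params.k4,
        "k5": cfg.nominal_params.k5,
        "k6": cfg.nominal_params.k6,
        "x1_0": cfg.nominal_x0.x1_0,
        "x2_0": cfg.nominal_x0.x2_0,
    }
    draws = []
    for _ in range(cfg.n_samples):
        d = {k: _truncated_normal(rng, m, cv * m) for k, m in nominal.items()}
        kd = d["k5"] - (d["k1"] + d["k2"])  # k3 = k1 + k2 by construction
        draws.append((d, kd))
    return draws


def feasibility_study(cfg: SensitivityStudyConfig) -> SensitivityStudyResult:
    """Monte-Carlo feasibility and OC deviation across the cv grid.

    Reproducible: all randomness flows from ``cfg.seed`` (one child stream
    per cv level).
    """
    nominal_oc = solve_closed_form(cfg.nominal_params, cfg.nominal_x0)
    ss = np.random.SeedSequence(cfg.seed)
    children = ss.spawn(len(cfg.cv_grid))
    rows = []
    for cv, child in zip(cfg.cv_grid, children):
        rng = np.random.default_rng(child)
        n_feasible = 0
        devs: dict[str, list[float]] = {
            k: [] for k in ("theta", "alpha1", "alpha2", "omega1", "omega2", "phi1", "phi2")
        }
        for d, kd in sample_parameters(cfg, cv, rng):
            if kd <= 0 or d["k2"] <= 0:
                continue
            try:
                p = KineticParameters(
                    k1=d["k1"], k2=d["k2"], k3=d["k1"] + d["k2"], k4=d["k4"],
                    k5=d["k5"], k6=d["k6"], kd=kd,
                )
                oc = solve_closed_form(p, InitialState(d["x1_0"], d["x2_0"]))
            except (ValueError, ZeroDivisionError):
                continue
            if not feasibility_check(oc, tol=cfg.feasibility_tol):
                continue
            n_feasible += 1
            devs["theta"].append(abs(oc.theta - nominal_oc.theta) / nominal_oc.theta)
            for i in (0, 1):
                if nominal_oc.alpha[i] > 0:
                    devs[f"alpha{i+1}"].append(
                        abs(oc.alpha[i] - nominal_oc.alpha[i]) / nominal_oc.alpha[i]
                    )
                if nominal_oc.omega[i] != 0:
                    devs[f"omega{i+1}"].append(
                        abs(oc.omega[i] - nominal_oc.omega[i]) / abs(nominal_oc.omega[i])
                    )
                devs[f"phi{i+1}"].append(abs(wrap_phase(oc.phi[i] - nominal_oc.phi[i])))
        f = n_feasible / cfg.n_samples
        row = {
            "cv": cv,
            "feasibility": f,
            "feasibility_se": math.sqrt(max(f * (1 - f), 0.0) / cfg.n_samples),
            "n_samples": cfg.n_samples,
        }
        for key, vals in devs.items():
            row[f"dev_{key}"] = float(np.mean(vals)) if vals else math.nan
            row[f"dev_{key}_sd"] = float(np.std(vals)) if vals else math.nan
        rows.append(row)
    sens = {k: analytic_frequency_sensitivity(cfg.nominal_params, k) for k in ("k2", "k3", "k5")}
    return SensitivityStudyResult(
        config=cfg, table=pd.DataFrame(rows), analytic_sensitivities=sens
    )
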