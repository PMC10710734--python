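"""Closed-form time-domain solution and oscillation characteristics (OCs).

Because the system dx/dt = A x + u has a zero trace and positive
determinant, every solution is an undamped sinusoid about the fixed point:

    x_n(t) = alpha_n * cos(theta*t + phi_n) + omega_n,      n in {1, 2}

with shared frequency theta = sqrt(k2*kd) and per-species amplitude
alpha_n, phase phi_n and DC offset omega_n.  The OCs are computed by the
homogeneous/particular decomposition: omega is the fixed point, and the
homogeneous part h(t) = x(t) - omega satisfies h(0) = x0 - omega,
h'(0) = A x0 + u, giving

    alpha_n = sqrt(h_n(0)^2 + (h_n'(0)/theta)^2)
    phi_n   = atan2(-h_n'(0)/theta, h_n(0))

The arctangent branch corrections (cond_1, cond_2, pi_n) that appear when
the phases are written as explicit inverse-tangent formulas are provided in
:func:`phase_corrections` and are verified against the atan2 branches
rather than used as the primary computation.

Two phase conventions are supported: "cos" as above, and "sin" where
x(t) = alpha*sin(theta*t + phi) + omega (the convention used for design
targets); they differ by a phase shift of pi/2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Literal

import numpy as np

from .params import (
    InitialState,
    KineticParameters,
    NoOscillationError,
    build_linear_system,
    fixed_point,
)

__all__ = [
    "OscillationCharacteristics",
    "PhaseCorrectionTerms",
    "Trajectory",
    "solve_closed_form",
    "phase_corrections",
    "evaluate_waveform",
    "convert_phase_convention",
    "feasibility_check",
    "large_k2_limit_signs",
    "wrap_phase",
]

Convention = Literal["cos", "sin"]


def wrap_phase(phi: float) -> float:
    """Wrap an angle into the canonical interval (-pi, pi]."""
    w = math.remainder(phi, 2 * math.pi)
    if w <= -math.pi:  # remainder returns [-pi, pi]; fold -pi onto +pi
        w += 2 * math.pi
    return w


@dataclass(frozen=True)
class OscillationCharacteristics:
    """Frequency, amplitudes, phases and DC offsets of both species.

    ``alpha``, ``phi`` and ``omega`` are (S1, S2) pairs; ``convention``
    states whether ``phi`` refers to the cos or the sin form.
    """

    theta: float
    alpha: tuple[float, float]
    phi: tuple[float, float]
    omega: tuple[float, float]
    convention: Convention = "cos"

    def __post_init__(self) -> None:
        if self.theta <= 0:
            raise ValueError("theta must be positive")
        if any(a < 0 for a in self.alpha):
            raise ValueError("amplitudes must be non-negative")

    def species(self, n: int) -> tuple[float, float, float]:
        """(alpha, phi, omega) of species n in {1, 2}."""
        return self.alpha[n - 1], self.phi[n - 1], self.omega[n - 1]

    def x0(self) -> np.ndarray:
        """Concentrations at t = 0 implied by the characteristics."""
        f = np.cos if self.convention == "cos" else np.sin
        return np.array(
            [a * f(p) + w for a, p, w in zip(self.alpha, self.phi, self.omega)]
        )

    def to_dict(self) -> dict:
        return {
            "theta": self.theta,
            "alpha": list(self.alpha),
            "phi": list(self.phi),
            "omega": list(self.omega),
            "convention": self.convention,
        }


@dataclass(frozen=True)
class PhaseCorrectionTerms:
    """The sign conditions and pi-corrections of the inverse-tangent phases.

    ``pi1`` is pi when ``cond1 < 0``; ``pi2`` is pi when ``cond2 > 0``;
    both are 0 otherwise.  ``T`` is the combined magnitude
    sqrt((k4 - k6)^2 + theta^2 (x1(0) + x2(0))^2) that governs the
    large-k2 feasibility limits.
    """

    cond1: float
    cond2: float
    pi1: float
    pi2: float
    T: float


@dataclass(frozen=True)
class Trajectory:
    """Sampled concentrations of both species on a strictly increasing grid."""

    times: np.ndarray
    x1: np.ndarray
    x2: np.ndarray
    source: Literal["closed_form", "ode"]

    def __post_init__(self) -> None:
        if len(self.times) != len(self.x1) or len(self.times) != len(self.x2):
            raise ValueError("times and concentration arrays must align")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")

    def stack(self) -> np.ndarray:
        """2 x n array with rows (S1, S2)."""
        return np.vstack([self.x1, self.x2])

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"time": self.times, "S1": self.x1, "S2": self.x2})


def solve_closed_form(p: KineticParameters, x0: InitialState) -> OscillationCharacteristics:
    """Oscillation characteristics of the initial value problem, cos convention.

    Raises :class:`NoOscillationError` when det(A) <= 0.  When a species
    does not oscillate (alpha_n = 0) its phase is 0 by convention.
    """
    sys = build_linear_system(p)
    if sys.det <= 0:
        raise NoOscillationError("determinant k2*kd must be positive")
    theta = sys.theta
    omega = np.array(fixed_point(sys))
    x = x0.as_array()
    h0 = x - omega
    hp0 = sys.A @ x + sys.u
    alpha = np.hypot(h0, hp0 / theta)
    phi = np.where(
        alpha > 0.0, np.arctan2(-hp0 / theta, h0), 0.0
    )
    return OscillationCharacteristics(
        theta=theta,
        alpha=(float(alpha[0]), float(alpha[1])),
        phi=(float(phi[0]), float(phi[1])),
        omega=(float(omega[0]), float(omega[1])),
        convention="cos",
    )


def phase_corrections(
    p: KineticParameters, x0: InitialState, theta: float
) -> PhaseCorrectionTerms:
    """Arctangent branch terms cond_1, cond_2, pi_1, pi_2 and the magnitude T.

    The cond expressions are evaluated term by term in their published
    explicit form (they simplify to h_1'(0)/theta and -h_2'(0)/theta, which
    is what ties them to the atan2 branches of :func:`solve_closed_form`).
    """
    if theta == 0:
        raise ZeroDivisionError("theta must be non-zero")
    k2, k4, k6, kd = p.k2, p.k4, p.k6, p.kd
    x1, x2 = x0.x1_0, x0.x2_0
    cond1 = (
        k2**2 * x1 / (k2 * theta + kd * theta)
        + k2**2 * x2 / (k2 * theta + kd * theta)
        + k2 * k4 * theta / (k2 * theta**2 + kd * theta**2)
        - 2 * k2 * k4 / (k2 * theta + kd * theta)
        - k2 * k6 * theta / (k2 * theta**2 + kd * theta**2)
        + k2 * k6 / (k2 * theta + kd * theta)
        + k2 * kd * x1 / (k2 * theta + kd * theta)
        + k4 * kd * theta / (k2 * theta**2 + kd * theta**2)
        - 2 * k4 * kd / (k2 * theta + kd * theta)
        + theta * x2 / (k2 + kd)
    )
    cond2 = k2 * x1 / theta + k2 * x2 / theta - k6 / theta + kd * x1 / theta
    pi1 = math.pi if cond1 < 0 else 0.0
    pi2 = math.pi if cond2 > 0 else 0.0
    T = math.sqrt(
        k4**2 - 2 * k4 * k6 + k6**2
        + theta**2 * x1**2 + 2 * theta**2 * x1 * x2 + theta**2 * x2**2
    )
    return PhaseCorrectionTerms(cond1=cond1, cond2=cond2, pi1=pi1, pi2=pi2, T=T)


def evaluate_waveform(oc: OscillationCharacteristics, times: Iterable[float]) -> Trajectory:
    """Sample the sinusoids x_n(t) = alpha_n f(theta*t + phi_n) + omega_n on a grid."""
    t = np.asarray(list(times) if not isinstance(times, np.ndarray) else times, dtype=float)
    f = np.cos if oc.convention == "cos" else np.sin
    vals = [a * f(oc.theta * t + p) + w for a, p, w in zip(oc.alpha, oc.phi, oc.omega)]
    return Trajectory(times=t, x1=vals[0], x2=vals[1], source="closed_form")


def convert_phase_convention(
    oc: OscillationCharacteristics, to: Convention
) -> OscillationCharacteristics:
    """Re-express the phases in the cos or sin convention.

    cos(x) = sin(x + pi/2), so the sin phase is the cos phase plus pi/2,
    normalized into (-pi, pi].  Waveforms are unchanged pointwise.
    """
    if to not in ("cos", "sin"):
        raise ValueError(f"unknown convention {to!r}")
    if to == oc.convention:
        return oc
    shift = math.pi / 2 if to == "sin" else -math.pi / 2
    phi = tuple(wrap_phase(p + shift) for p in oc.phi)
    return replace(oc, phi=phi, convention=to)


def feasibility_check(oc: OscillationCharacteristics, tol: float = 1e-9) -> bool:
    """True when concentrations stay non-negative: omega_n >= alpha_n.

    A relative tolerance admits boundary-grazing oscillators whose trough
    just touches zero (omega_n = alpha_n), which are legitimate solutions.
    """
    if tol < 0:
        raise ValueError("tol must be non-negative")
    return all(
        w >= a - tol * max(1.0, abs(w)) for a, w in zip(oc.alpha, oc.omega)
    )


def large_k2_limit_signs(
    k4: float, k6: float, theta: float, x0: InitialState
) -> tuple[float, float]:
    """Signs of lim_{k2->inf} (omega_n - alpha_n) for n = 1, 2.

    In that limit omega_1 - alpha_1 diverges with the sign of
    (-k4 + k6 - T) and omega_2 - alpha_2 with the sign of (k4 - k6 - T),
    where T = sqrt((k4-k6)^2 + theta^2 (x1(0)+x2(0))^2).  Since T dominates
    both brackets unless it vanishes, at most one species can remain
    non-negative: the constraint cannot be satisfied for both by pushing k2.
    """
    if theta <= 0:
        raise ValueError("theta must be positive")
    T = math.sqrt((k4 - k6) ** 2 + theta**2 * (x0.x1_0 + x0.x2_0) ** 2)
    return (float(np.sign(-k4 + k6 - T)), float(np.sign(k4 - k6 - T)))
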