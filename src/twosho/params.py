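"""Kinetic parameters and the linear system of the two-species harmonic oscillator.

The network couples two species S1, S2 through six reactions:

    R1: S1 -> S2        rate k1*S1   (mass action)
    R2: S2 -> S1        rate k2*S2   (mass action)
    R3: S1 -> 2 S1      rate k3*S1   (autocatalysis, positive feedback)
    R4: S1 -> 0         rate k4      (zeroth order degradation)
    R5: S2 -> 0         rate k5*S1   (degradation of S2 controlled by S1)
    R6: 0  -> S2        rate k6      (zeroth order synthesis)

Its dynamics are the linear system  dx/dt = A x + u  with

    A = [[ k2,       k2 ],          u = (-k4, k6)
         [ -k2 - kd, -k2 ]]

provided the dependency constraints k3 = k1 + k2 and k5 = k3 + kd hold.
These force trace(A) = 0 and det(A) = k2*kd > 0, so the eigenvalues are the
pure imaginary pair +/- i*sqrt(k2*kd) and every solution is a sustained
sinusoid.  k3 and k5 are therefore *dependent* parameters; the free ones are
k1, k2, k4, k6, kd and the two initial concentrations.

Units are abstract: k1, k2, k3, k5 and kd are first-order constants
[1/time]; k4 and k6 are zeroth-order rates [conc/time].
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Union

import numpy as np
import yaml

__all__ = [
    "ConstraintViolation",
    "NoOscillationError",
    "KineticParameters",
    "InitialState",
    "LinearSystem",
    "ConstraintReport",
    "derive_dependent_parameters",
    "build_linear_system",
    "frequency",
    "fixed_point",
    "validate_constraints",
    "load_parameters",
    "dump_parameters",
]

#: relative tolerance used when verifying the dependency constraints
DEPENDENCY_RTOL = 1e-9


class ConstraintViolation(ValueError):
    """A kinetic-parameter set violates the oscillator constraints."""


class NoOscillationError(ValueError):
    """The parameter set cannot oscillate (det(A) = k2*kd <= 0)."""


def _close(a: float, b: float, rtol: float = DEPENDENCY_RTOL) -> bool:
    return abs(a - b) <= rtol * max(1.0, abs(a), abs(b))


@dataclass(frozen=True)
class KineticParameters:
    """The six kinetic constants plus the derived difference kd = k5 - k3.

    The constructor accepts the full set but verifies the dependency
    constraints k3 = k1 + k2 and k5 = k3 + kd to a relative tolerance of
    1e-9; use :func:`derive_dependent_parameters` to build a set from the
    independent constants only.
    """

    k1: float
    k2: float
    k3: float
    k4: float
    k5: float
    k6: float
    kd: float

    def __post_init__(self) -> None:
        for name in ("k1", "k2", "k3", "k4", "k5", "k6"):
            if getattr(self, name) < 0:
                raise ConstraintViolation(f"{name} must be non-negative")
        if self.k2 <= 0:
            raise ConstraintViolation("k2 must be positive")
        if self.kd <= 0:
            raise ConstraintViolation("kd must be positive (k5 > k3 required)")
        if not _close(self.k3, self.k1 + self.k2):
            raise ConstraintViolation(
                f"dependency violated: k3={self.k3} != k1+k2={self.k1 + self.k2}"
            )
        if not _close(self.k5, self.k3 + self.kd):
            raise ConstraintViolation(
                f"dependency violated: k5={self.k5} != k3+kd={self.k3 + self.kd}"
            )

    @property
    def theta(self) -> float:
        """Angular frequency sqrt(k2*kd) [rad/time]."""
        return frequency(self.k2, self.kd)

    def replace(self, **kwargs) -> "KineticParameters":
        """Return a copy with independent constants replaced and k3, k5 rederived."""
        vals = dict(k1=self.k1, k2=self.k2, k4=self.k4, k6=self.k6, kd=self.kd)
        vals.update(kwargs)
        return derive_dependent_parameters(
            vals["k1"], vals["k2"], vals["kd"], k4=vals["k4"], k6=vals["k6"]
        )

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in ("k1", "k2", "k3", "k4", "k5", "k6", "kd")}


@dataclass(frozen=True)
class InitialState:
    """Initial concentrations x1(0), x2(0) of the two species."""

    x1_0: float
    x2_0: float

    def __post_init__(self) -> None:
        if self.x1_0 < 0 or self.x2_0 < 0:
            raise ConstraintViolation("initial concentrations must be non-negative")

    def as_array(self) -> np.ndarray:
        return np.array([self.x1_0, self.x2_0], dtype=float)


@dataclass(frozen=True)
class LinearSystem:
    """The matrix form dx/dt = A x + u of the network, with its spectrum.

    Eigenvalues are stored as a complex pair even though they are pure
    imaginary by construction, so that perturbed near-degenerate systems
    can be analyzed uniformly.
    """

    A: np.ndarray
    u: np.ndarray
    trace: float
    det: float
    eigenvalues: tuple[complex, complex]
    params: KineticParameters = field(repr=False)

    @property
    def theta(self) -> float:
        return math.sqrt(self.det)


def derive_dependent_parameters(
    k1: float, k2: float, kd: float, *, k4: float = 0.0, k6: float = 0.0
) -> KineticParameters:
    """Build a full parameter set from the independent constants.

    k3 = k1 + k2 and k5 = k3 + kd are computed; k4 and k6 are taken as
    provided.  Raises :class:`ConstraintViolation` for non-positive k2 or kd.
    """
    if k2 <= 0:
        raise ConstraintViolation("k2 must be positive")
    if kd <= 0:
        raise ConstraintViolation("kd must be positive")
    k3 = k1 + k2
    return KineticParameters(k1=k1, k2=k2, k3=k3, k4=k4, k5=k3 + kd, k6=k6, kd=kd)


def frequency(k2: float, kd: float) -> float:
    """Oscillation frequency theta = sqrt(k2*kd) [rad/time].

    Of the two square roots only the non-negative one is returned; the sign
    ambiguity is carried by the phase, which is a separate oscillation
    characteristic.
    """
    if k2 * kd <= 0:
        raise NoOscillationError("k2*kd must be positive for oscillation")
    return math.sqrt(k2 * kd)


def build_linear_system(p: KineticParameters) -> LinearSystem:
    """Assemble A, u and the spectral quantities for a valid parameter set."""
    A = np.array([[p.k2, p.k2], [-p.k2 - p.kd, -p.k2]], dtype=float)
    u = np.array([-p.k4, p.k6], dtype=float)
    tau = float(A[0, 0] + A[1, 1])
    delta = float(A[0, 0] * A[1, 1] - A[0, 1] * A[1, 0])
    lam = np.linalg.eigvals(A)
    # order as (+i theta, -i theta) for reproducibility
    lam = sorted((complex(v) for v in lam), key=lambda z: -z.imag)
    return LinearSystem(A=A, u=u, trace=tau, det=delta, eigenvalues=(lam[0], lam[1]), params=p)


def fixed_point(sys: LinearSystem) -> tuple[float, float]:
    """The stationary point of dx/dt = A x + u, i.e. the solution of A x = -u.

    For this network it has the closed form x1* = (k6 - k4)/kd and
    x2* = k4/k2 - x1*.  It equals the DC offsets (omega_1, omega_2) of the
    oscillation and may have negative components, which flags an infeasible
    parameter set.
    """
    if abs(sys.det) < 1e-300:
        raise np.linalg.LinAlgError("singular system: no unique fixed point")
    p = sys.params
    w1 = (p.k6 - p.k4) / p.kd
    w2 = p.k4 / p.k2 - w1
    return (w1, w2)


@dataclass(frozen=True)
class ConstraintReport:
    """Pass/fail record for the structural oscillator constraints.

    C1 (linear rate laws) holds by construction of this network.  C2
    (non-negative concentrations) depends on the full solution and is
    checked by :func:`twosho.closedform.feasibility_check`.  C3 is a zero
    trace, C4 a positive determinant.
    """

    c1: bool
    c3: bool
    c4: bool
    trace: float
    det: float

    @property
    def all_pass(self) -> bool:
        return self.c1 and self.c3 and self.c4


def validate_constraints(p: KineticParameters, x0: InitialState | None = None) -> ConstraintReport:
    """Evaluate the structural constraints C1, C3, C4 for a parameter set."""
    sys = build_linear_system(p)
    return ConstraintReport(
        c1=True,
        c3=sys.trace == 0.0,
        c4=sys.det > 0.0,
        trace=sys.trace,
        det=sys.det,
    )


# ---------------------------------------------------------------------------
# JSON / YAML configuration (independent parameters only)

_SCHEMA_KEYS = {"k1", "k2", "k4", "k6", "kd", "x1_0", "x2_0"}


def load_parameters(source: Union[str, Path, dict]) -> tuple[KineticParameters, InitialState]:
    """Load {k1, k2, k4, k6, kd, x1_0, x2_0} from a dict or JSON/YAML file.

    Only independent parameters are accepted; k3 and k5 are derived.
    """
    if isinstance(source, (str, Path)):
        text = Path(source).read_text()
        data = yaml.safe_load(text)  # YAML is a JSON superset
    else:
        data = dict(source)
    missing = _SCHEMA_KEYS - set(data)
    if missing:
        raise KeyError(f"missing parameter keys: {sorted(missing)}")
    extra = set(data) - _SCHEMA_KEYS
    if extra:
        raise KeyError(f"unknown parameter keys: {sorted(extra)}")
    p = derive_dependent_parameters(
        float(data["k1"]), float(data["k2"]), float(data["kd"]),
        k4=float(data["k4"]), k6=float(data["k6"]),
    )
    return p, InitialState(float(data["x1_0"]), float(data["x2_0"]))


def dump_parameters(p: KineticParameters, x0: InitialState, path: Union[str, Path]) -> None:
    """Write the independent parameters as JSON (round-trips with load_parameters)."""
    data = {
        "k1": p.k1, "k2": p.k2, "k4": p.k4, "k6": p.k6, "kd": p.kd,
        "x1_0": x0.x1_0, "x2_0": x0.x2_0,
    }
    Path(path).write_text(json.dumps(data, indent=2))
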