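"""Numerical integration oracle and model exchange (Antimony / SBML).

The integrator solves dx/dt = A x + u directly from the assembled linear
system; the reaction-by-reaction form of the network exists only in the
exporters.  This keeps the numerical oracle exact and fast while the
exported models carry the full six-reaction structure for exchange with
other tools.

The module also ships minimal readers for the two exported formats that
rebuild the ODE right-hand side from the *reaction* representation
(stoichiometry times parsed rate laws).  Re-integrating that reconstruction
and comparing against :func:`integrate_ode` is an end-to-end check that the
exported documents encode the intended network.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
import sympy as sp
from lxml import etree
from scipy.integrate import solve_ivp

from .closedform import Trajectory, evaluate_waveform, solve_closed_form
from .params import InitialState, KineticParameters, build_linear_system

__all__ = [
    "SimulationConfig",
    "integrate_ode",
    "verify_agreement",
    "export_antimony",
    "export_sbml",
    "network_rhs_from_antimony",
    "network_rhs_from_sbml",
    "default_config",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Time grid and solver tolerances for the ODE oracle."""

    t_end: float
    n_points: int = 400
    rtol: float = 1e-12
    atol: float = 1e-12

    def __post_init__(self) -> None:
        if self.t_end <= 0:
            raise ValueError("t_end must be positive")
        if self.n_points < 2:
            raise ValueError("n_points must be at least 2")

    @property
    def times(self) -> np.ndarray:
        return np.linspace(0.0, self.t_end, self.n_points)


def default_config(p: KineticParameters, n_periods: float = 2.0,
                   points_per_period: int = 200) -> SimulationConfig:
    """Grid covering ``n_periods`` oscillation periods at the given density."""
    period = 2 * np.pi / p.theta
    return SimulationConfig(
        t_end=n_periods * period, n_points=max(2, int(round(n_periods * points_per_period)))
    )


def integrate_ode(
    p: KineticParameters, x0: InitialState, cfg: SimulationConfig
) -> Trajectory:
    """Integrate dx/dt = A x + u from x0 with a high-order explicit solver.

    Concentrations are not clamped: infeasible parameter sets legitimately
    produce negative values and the oracle must report them.
    """
    sys = build_linear_system(p)
    A, u = sys.A, sys.u

    def rhs(_t: float, x: np.ndarray) -> np.ndarray:
        return A @ x + u

    sol = solve_ivp(
        rhs,
        (0.0, cfg.t_end),
        x0.as_array(),
        t_eval=cfg.times,
        method="DOP853",
        rtol=cfg.rtol,
        atol=cfg.atol,
    )
    if not sol.success:
        raise RuntimeError(f"ODE integration failed: {sol.message}")
    return Trajectory(times=sol.t, x1=sol.y[0], x2=sol.y[1], source="ode")


def verify_agreement(
    p: KineticParameters, x0: InitialState, cfg: SimulationConfig | None = None
) -> float:
    """Max absolute deviation between the closed form and the ODE oracle.

    The two pipelines share nothing beyond (A, u): the closed form goes
    through the fixed point and the homogeneous solution, the oracle
    through numerical integration.
    """
    if cfg is None:
        cfg = default_config(p)
    oc = solve_closed_form(p, x0)
    pred = evaluate_waveform(oc, cfg.times)
    sim = integrate_ode(p, x0, cfg)
    return float(np.max(np.abs(pred.stack() - sim.stack())))


# ---------------------------------------------------------------------------
# Model export

_REACTIONS = (
    # (id, reactants, products, modifiers, rate template)
    ("R1", {"S1": 1}, {"S2": 1}, (), "k1 * S1"),
    ("R2", {"S2": 1}, {"S1": 1}, (), "k2 * S2"),
    ("R3", {"S1": 1}, {"S1": 2}, (), "k3 * S1"),
    ("R4", {"S1": 1}, {}, (), "k4"),
    ("R5", {"S2": 1}, {}, ("S1",), "k5 * S1"),
    ("R6", {}, {"S2": 1}, (), "k6"),
)


def _fmt(x: float) -> str:
    return repr(float(x))


def export_antimony(p: KineticParameters, x0: InitialState) -> str:
    """Antimony text for the six-reaction network with verbatim parameter values."""
    lines = ["model twosho"]
    for rid, reac, prod, _mods, rate in _REACTIONS:
        lhs = " + ".join(f"{n} {s}" if n > 1 else s for s, n in reac.items())
        rhs = " + ".join(f"{n} {s}" if n > 1 else s for s, n in prod.items())
        lines.append(f"  {rid}: {lhs} -> {rhs}; {rate}")
    lines.append("")
    for name in ("k1", "k2", "k3", "k4", "k5", "k6"):
        lines.append(f"  {name} = {_fmt(getattr(p, name))}")
    lines.append(f"  S1 = {_fmt(x0.x1_0)}")
    lines.append(f"  S2 = {_fmt(x0.x2_0)}")
    lines.append("end")
    return "\n".join(lines) + "\n"


_SBML_NS = "http://www.sbml.org/sbml/level3/version2/core"
_MATHML_NS = "http://www.w3.org/1998/Math/MathML"


def _mathml(expr: str) -> etree._Element:
    """MathML <math> element for a product-of-symbols/number rate law."""
    math = etree.Element(f"{{{_MATHML_NS}}}math")
    factors = [f.strip() for f in expr.split("*")]

    def node(tok: str) -> etree._Element:
        try:
            float(tok)
        except ValueError:
            ci = etree.Element(f"{{{_MATHML_NS}}}ci")
            ci.text = f" {tok} "
            return ci
        cn = etree.Element(f"{{{_MATHML_NS}}}cn")
        cn.text = f" {tok} "
        return cn

    if len(factors) == 1:
        math.append(node(factors[0]))
    else:
        ap = etree.SubElement(math, f"{{{_MATHML_NS}}}apply")
        etree.SubElement(ap, f"{{{_MATHML_NS}}}times")
        for f in factors:
            ap.append(node(f))
    return math


def export_sbml(p: KineticParameters, x0: InitialState) -> str:
    """SBML Level 3 Version 2 document for the network (serialized XML)."""
    sbml = etree.Element(f"{{{_SBML_NS}}}sbml", level="3", version="2")
    model = etree.SubElement(sbml, f"{{{_SBML_NS}}}model", id="twosho")

    comps = etree.SubElement(model, f"{{{_SBML_NS}}}listOfCompartments")
    etree.SubElement(
        comps, f"{{{_SBML_NS}}}compartment",
        id="cell", size="1", spatialDimensions="3", constant="true",
    )

    species = etree.SubElement(model, f"{{{_SBML_NS}}}listOfSpecies")
    for sid, conc in (("S1", x0.x1_0), ("S2", x0.x2_0)):
        etree.SubElement(
            species, f"{{{_SBML_NS}}}species",
            id=sid, compartment="cell", initialConcentration=_fmt(conc),
            hasOnlySubstanceUnits="true", boundaryCondition="false", constant="false",
        )

    pars = etree.SubElement(model, f"{{{_SBML_NS}}}listOfParameters")
    for name in ("k1", "k2", "k3", "k4", "k5", "k6"):
        etree.SubElement(
            pars, f"{{{_SBML_NS}}}parameter",
            id=name, value=_fmt(getattr(p, name)), constant="true",
        )

    reactions = etree.SubElement(model, f"{{{_SBML_NS}}}listOfReactions")
    for rid, reac, prod, mods, rate in _REACTIONS:
        rx = etree.SubElement(
            reactions, f"{{{_SBML_NS}}}reaction", id=rid, reversible="false"
        )
        if reac:
            lo = etree.SubElement(rx, f"{{{_SBML_NS}}}listOfReactants")
            for sid, n in reac.items():
                etree.SubElement(
                    lo, f"{{{_SBML_NS}}}speciesReference",
                    species=sid, stoichiometry=str(n), constant="true",
                )
        if prod:
            lo = etree.SubElement(rx, f"{{{_SBML_NS}}}listOfProducts")
            for sid, n in prod.items():
                etree.SubElement(
                    lo, f"{{{_SBML_NS}}}speciesReference",
                    species=sid, stoichiometry=str(n), constant="true",
                )
        for sid in mods:
            lo = rx.find(f"{{{_SBML_NS}}}listOfModifiers")
            if lo is None:
                lo = etree.SubElement(rx, f"{{{_SBML_NS}}}listOfModifiers")
            etree.SubElement(lo, f"{{{_SBML_NS}}}modifierSpeciesReference", species=sid)
        kl = etree.SubElement(rx, f"{{{_SBML_NS}}}kineticLaw")
        kl.append(_mathml(rate))

    return etree.tostring(
        sbml, xml_declaration=True, encoding="UTF-8", pretty_print=True
    ).decode()


# ---------------------------------------------------------------------------
# Readers: rebuild the ODE from the reaction representation

def _rhs_from_network(
    rate_exprs: dict[str, sp.Expr],
    stoich: dict[str, dict[str, int]],
    constants: dict[str, float],
) -> Callable[[float, np.ndarray], np.ndarray]:
    """RHS f(t, x) = N v(x) from per-reaction rate laws and net stoichiometry."""
    s1, s2 = sp.symbols("S1 S2")
    subs = {sp.Symbol(k): v for k, v in constants.items()}
    rates = {rid: sp.lambdify((s1, s2), e.subs(subs), "numpy") for rid, e in rate_exprs.items()}

    def rhs(_t: float, x: np.ndarray) -> np.ndarray:
        v = {rid: f(x[0], x[1]) for rid, f in rates.items()}
        return np.array(
            [
                sum(stoich[rid].get("S1", 0) * v[rid] for rid in v),
                sum(stoich[rid].get("S2", 0) * v[rid] for rid in v),
            ],
            dtype=float,
        )

    return rhs


def network_rhs_from_antimony(text: str):
    """Parse an exported Antimony model back into (rhs, x0 array).

    Understands the subset this package emits: irreversible reactions with
    integer stoichiometries and algebraic rate laws, plus assignments.
    """
    rate_exprs: dict[str, sp.Expr] = {}
    stoich: dict[str, dict[str, int]] = {}
    constants: dict[str, float] = {}
    inits = {"S1": 0.0, "S2": 0.0}
    for raw in text.splitlines():
        line = raw.strip()
        if not line or line.startswith(("model", "end", "//")):
            continue
        if ":" in line and "->" in line:
            rid, rest = line.split(":", 1)
            eqn, rate = rest.split(";")
            lhs, rhs_side = eqn.split("->")
            net: dict[str, int] = {}
            for side, sign in ((lhs, -1), (rhs_side, +1)):
                for term in side.split("+"):
                    term = term.strip()
                    if not term:
                        continue
                    parts = term.split()
                    n, sid = (int(parts[0]), parts[1]) if len(parts) == 2 else (1, parts[0])
                    net[sid] = net.get(sid, 0) + sign * n
            stoich[rid.strip()] = net
            rate_exprs[rid.strip()] = sp.sympify(rate.strip())
        elif "=" in line:
            name, val = (s.strip() for s in line.split("="))
            if name in inits:
                inits[name] = float(val)
            else:
                constants[name] = float(val)
    rhs = _rhs_from_network(rate_exprs, stoich, constants)
    return rhs, np.array([inits["S1"], inits["S2"]])


def _mathml_to_sympy(elem: etree._Element) -> sp.Expr:
    tag = etree.QName(elem).localname
    if tag == "math":
        return _mathml_to_sympy(elem[0])
    if tag == "ci":
        return sp.Symbol(elem.text.strip())
    if tag == "cn":
        return sp.Float(elem.text.strip())
    if tag == "apply":
        op = etree.QName(elem[0]).localname
        args = [_mathml_to_sympy(c) for c in elem[1:]]
        if op == "times":
            return sp.Mul(*args)
        if op == "plus":
            return sp.Add(*args)
        raise ValueError(f"unsupported MathML operator {op!r}")
    raise ValueError(f"unsupported MathML element {tag!r}")


def network_rhs_from_sbml(document: str):
    """Parse an exported SBML document back into (rhs, x0 array)."""
    root = etree.fromstring(document.encode())
    ns = {"s": _SBML_NS}
    model = root.find("s:model", ns)
    inits = {
        sp_el.get("id"): float(sp_el.get("initialConcentration"))
        for sp_el in model.findall("s:listOfSpecies/s:species", ns)
    }
    constants = {
        par.get("id"): float(par.get("value"))
        for par in model.findall("s:listOfParameters/s:parameter", ns)
    }
    rate_exprs: dict[str, sp.Expr] = {}
    stoich: dict[str, dict[str, int]] = {}
    for rx in model.findall("s:listOfReactions/s:reaction", ns):
        rid = rx.get("id")
        net: dict[str, int] = {}
        for ref in rx.findall("s:listOfReactants/s:speciesReference", ns):
            net[ref.get("species")] = net.get(ref.get("species"), 0) - int(
                float(ref.get("stoichiometry"))
            )
        for ref in rx.findall("s:listOfProducts/s:speciesReference", ns):
            net[ref.get("species")] = net.get(ref.get("species"), 0) + int(
                float(ref.get("stoichiometry"))
            )
        stoich[rid] = net
        math_el = rx.find(f"{{{_SBML_NS}}}kineticLaw/{{{_MATHML_NS}}}math")
        rate_exprs[rid] = _mathml_to_sympy(math_el)
    rhs = _rhs_from_network(rate_exprs, stoich, constants)
    return rhs, np.array([inits["S1"], inits["S2"]])
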