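# Methods

## Model and assumptions

The package studies a closed-form-solvable oscillator built from six
reactions on two species. All rate laws are linear in the concentrations
(first-order mass action or zeroth-order constant rates), so the dynamics
are exactly ẋ = A x + u; there is no approximation anywhere in the forward
model. Two structural constraints make the system a harmonic oscillator:
the trace of A must vanish, which forces the dependency k3 = k1 + k2
between the autocatalysis and interconversion constants, and the
determinant must be positive, which forces k5 = k3 + kd with kd > 0 (the
negative feedback through k5 must exceed the positive feedback through k3).
k3 and k5 are therefore *dependent* parameters: constructors always derive
them, and parameter sets supplied with explicit k3/k5 are verified against
the dependencies to a relative tolerance of 1e-9 and rejected otherwise.
Because the eigenvalues sit exactly on the imaginary axis, the oscillation
is not asymptotically stable — it is a conservative center, and amplitudes
are set by the initial conditions, as for any harmonic oscillator.

Units are deliberately abstract. First-order constants (k1, k2, k3, k5,
kd) carry [1/time]; zeroth-order rates (k4, k6) carry [concentration/time];
nothing in the mathematics fixes the time or concentration scale.

## Closed-form solution

The solution is computed by the homogeneous/particular decomposition rather
than by transcribing per-characteristic formulas: the DC offset vector ω is
the fixed point of the affine system (closed form ω1 = (k6−k4)/kd,
ω2 = k4/k2 − ω1), and the homogeneous part h(t) = x(t) − ω with h(0) and
h′(0) = A x(0) + u yields

    α_n = √(h_n(0)² + (h_n′(0)/θ)²),  φ_n = atan2(−h_n′(0)/θ, h_n(0)).

This route is verified three independent ways: the waveform satisfies the
ODE residual test (central differences on a fine grid), it matches
high-accuracy numerical integration to below 1e-8 over two periods across
random parameter sets, and the published branch-correction terms for the
inverse-tangent phase formulas (cond₁, cond₂ with their π-corrections)
agree with the atan2 branches — the cond expressions simplify algebraically
to ±h′(0)/θ, which is exactly the atan2 second/first-argument structure.

Phases are canonicalized to (−π, π]. Two conventions coexist in practice
(cos for the solution, sin for design targets); both are supported
explicitly and differ by a π/2 shift. When a species does not oscillate
(α_n = 0) its phase is 0 by convention. Feasibility (concentrations never
negative) is equivalent to ω_n ≥ α_n and is checked with a relative
tolerance of 1e-9 so that boundary-grazing oscillators — whose troughs
touch zero exactly, a legitimate and common design outcome when the target
offset equals the target amplitude — count as feasible.

A consequence worth stating because it is convention-dependent: in the
large-k2 limit with fixed frequency, kd = θ²/k2 → 0 makes x1 + x2 nearly
conserved, so the oscillating parts of the two species cancel. With
non-negative amplitudes this appears as a phase gap of exactly π
(antiphase); the same motion described with signed amplitudes would have
equal phases and opposite-sign amplitudes. Likewise, the large-k2
feasibility limits sign(−k4+k6−T) and sign(k4−k6−T) with
T = √((k4−k6)² + θ²(x1(0)+x2(0))²) can never both be non-negative — indeed
T ≥ |k4−k6| algebraically, so neither bracket is ever positive unless both
initial concentrations vanish: pushing k2 cannot rescue feasibility.

## Numerical oracle and model exchange

The simulator integrates (A, u) directly with an explicit 8th-order
Runge–Kutta method (DOP853) at rtol = atol = 1e-12 on 200 points per
period. The tight tolerance keeps the closed-form/integration deviation
near 1e-10 even for amplitudes of order 100; at 1e-10 tolerances the
deviation for such regimes sits right at the 1e-8 comparison bound, which
is why the default is tighter. The reaction-by-reaction form of the network
exists in the exporters (Antimony text and SBML Level 3 Version 2 built
with lxml). The package ships readers for the exact subset it emits; tests
rebuild the ODE from the parsed *reaction* representation (net
stoichiometry × sympy-parsed rate laws), re-integrate it, and compare with
the linear-system integrator, so the exported documents are verified to
encode the intended network end to end. SBML documents are checked for
well-formedness and structure (2 species, 6 reactions, verbatim parameter
values); full XML-schema validation is out of scope.

## Design algorithm

Designing to a target x*(t) = α* sin(θ*t + φ*) + ω* is a 5-dimensional
bounded least-squares problem after two exact reductions: k1 := 1 (it never
enters the characteristics) and kd := θ*²/k2 (so the achieved frequency is
θ* identically — frequency design error is structurally zero). The loss is
the sum of squared waveform deviations on a grid of 2 periods × 10 points
per period (configurable; at least two full cycles are needed so the fit
sees amplitude, phase and offset independently). Hard non-negativity of
both concentrations is relaxed into penalty residuals w·min(x_n(t), 0) with
w = 1000 by default — large enough that a unit-depth violation costs 1e6,
dominating ordinary residuals at amplitudes up to 100.

The optimizer is lmfit's bounded trust-region-reflective least squares with
k_i ∈ [0, 1000] (k2 floored at 1e-6) and initial concentrations bounded by
max(1000, 4(α*+ω*)). Multi-start: restarts alternate between uniform draws
over the bounds (concentrations drawn in [0, 2(α*+ω*)]) and *informed*
starts that, for a random log-uniform k2 near the target frequency, invert
the amplitude/phase/offset relations in closed form so the candidate
species already matches the target exactly (clipped to the bounds when the
exact solution lies outside them). The informed starts matter for
large-amplitude/extreme-frequency targets where blind uniform starts
frequently land in local minima; the uniform starts preserve global
exploration. Both species are fitted independently and the one with the
smaller penalized loss is returned (ties favor S1); restarts stop early
when a loss below 1e-16 is reached. All draws flow from a single seed, so
results are bit-reproducible. Ten restarts is the default — on a 3×3×4
grid of targets spanning θ*, α* ∈ [0.1, 10] and four phases, eight restarts
already bring every cell's amplitude and phase errors below 1e-8.

Design errors follow the study conventions: amplitude error (α̂−α*)/α*
(−1 means the chosen species is constant), phase error as a fraction of a
cycle wrapped into (−0.5, 0.5]. The study tables flag a feasibility design
error when a concentration is negative at an evaluation grid point, with a
floating-point floor of 1e-9·max(1, α*+ω*) so that exact zero-grazing fits
are not misclassified by rounding noise.

## Sensitivity analysis

The frequency admits exact relative sensitivities: S_k2 = 1/2,
S_k3 = −k3/(2(k5−k3)), S_k5 = k5/(2(k5−k3)), zero for every other
parameter; S_k3 + S_k5 = 1/2 identically, and a central-difference
evaluator confirms the formulas to 1e-6. The other characteristics are
studied by Monte Carlo around a nominal oscillator (k1 = 1.00, k2 = 3.91,
k5 = 15.00, k6 = 92.2, x(0) = (5.00, 10.49), with k4 = k6 − kd·5.00 =
41.75 so that ω1 = 5.00 exactly; a second variant with k4 = 4.77 is kept
for reference but has a negative S2 offset and is not a valid oscillator).
Each realizable parameter (k1, k2, k4, k5, k6 and both initial
concentrations) is drawn independently from a normal distribution with
mean at nominal and standard deviation cv·nominal — cv spanning 0.01–0.2,
the reported range of experimental variability for kinetic constants —
truncated at zero by rejection (clipping would pile probability mass at
zero). k3 is recomputed as k1 + k2 per draw, because the network
construction enforces that identity; kd = k5 − k3 may then be non-positive,
which counts the draw as infeasible. Feasibility additionally requires
ω_n ≥ α_n for both species (same 1e-9 tolerance as above). 400 draws per
cv is the default study size; feasibility fractions carry binomial
standard errors (±2 SE ≈ ±0.05 at n = 400 near f = 0.5).

A caveat the Monte-Carlo results make visible: the nominal oscillator
grazes the feasibility boundary (ω2 − α2 ≈ 0.0093), so at small cv the
feasibility fraction is necessarily close to one half — perturbations fall
on either side of the boundary almost symmetrically. The measured fractions
here are ≈0.50 at cv = 0.01 and ≈0.30 at cv = 0.2. The success probability
of m independent construction attempts is p(m, f) = 1 − (1−f)^m; at the
published per-try feasibilities this gives p(4, 0.57) = 0.966 and
p(6, 0.33) = 0.910, both clearing a 90% success bound.

## Synthetic study inputs

There are no external datasets: study inputs are generated by
`twosho.fixtures`. The design grid places θ* and α* geometrically on
[0.1, 100] (8 increments per axis at full scale — three decimal orders of
magnitude; reduced grids keep the endpoints and geometric spacing) with
ω* = α* and phases {0, π/2, π, 2π/3}, the values most exposed to
inverse-tangent branch issues. The four verification regimes span slow and
fast frequencies, zero and nonzero k1, and order-1 to order-100 offsets.
These fixtures exercise the mathematics fully — the model is exact, so
there is no distributional realism at stake — but passing them says
nothing about wet-lab realizability of any particular rate constant, which
depends on chemistry outside this package's scope.

## Known limitations

* Two species only; no attempt to generalize the construction to larger
  networks.
* The designer fits a single sinusoid (one chosen species), not both
  species' characteristics simultaneously, and guarantees no global
  optimum — only a multi-start best fit.
* Deterministic ODE semantics throughout; no stochastic (SSA) simulation.
* The center is structurally non-robust: any perturbation that breaks
  trace(A) = 0 turns the oscillation into a spiral. The sensitivity study
  quantifies the consequences for feasibility but the package does not
  model damped/growing regimes beyond flagging them infeasible.
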