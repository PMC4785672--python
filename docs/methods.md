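# Methods

This note records the mathematical model of the analyses, the numerical
choices, and what the built-in fixtures do and do not establish.

## Solutions of interest

All analyses linearise about a reference trajectory g(t, k) of
dx/dt = f(t, x, k).

**Autonomous limit cycle.** After pre-integrating (default 20 estimated
periods) to reach the attractor, the cycle is refined by Newton shooting on
the periodic boundary-value problem with unknowns (x₀, τ):

    x(τ; x₀) − x₀ = 0,        f₁(x₀) = 0  with  ẍ₁(0) < 0.

The second (phase anchor) equation starts the orbit at a peak of the first
variable, which removes the time-translation degeneracy; the bordered
(n+1)×(n+1) Newton system is nonsingular even though I − C(0,τ) is singular
along the flow.  Shooting (rather than collocation) was chosen because the
same flow-with-state-transition-matrix integrations are needed downstream
anyway; the convergence contract is a boundary defect ≤ 1e−8 (typically
~1e−14 at the default tolerances).

**Entrained orbit.** For a model with periodic forcing of period T, the orbit
is the fixed point of the period-T return map, solved by Newton iteration
with Jacobian Φ(T) − I.  The period is T *by construction* (bit-exact), which
is what entrainment means; an error is raised if any Floquet multiplier has
modulus ≥ 1.  All integrations split the time span at forcing switch times so
discontinuities never sit inside a solver step; forcing windows are half-open
[start, end), making evaluation at switch times deterministic.

**Signalling transient.** The unstimulated equilibrium is seeded by a long
integration and polished by damped Newton on f(x) = 0 (residual ≤ 1e−10);
it must be linearly stable.  The stimulated trajectory then starts from this
fixed initial condition.

Default solver: DOP853 with rtol 1e−9, atol 1e−12 (stiff alternatives Radau/
LSODA selectable via `method=`).  Periodic solutions are sampled on 241
equally spaced grid points per period; doubling the density changes periodic
orbits by ≲ 1e−6, and all response quantities are grid-converged well below
their stated tolerances.

## Variational machinery

State-transition matrices Φ(t_l → t_{l+1}) are integrated per grid interval
jointly with the trajectory, and composed on demand into fundamental matrices
C(s, t).  Storing per-step matrices is O(N n²) versus O(N² n²) for all pairs,
and composition reproduces any C(s, t) at the cost of ≤ N−1 small matrix
products (verified against the cocycle identity and the Liouville
determinant formula).  The monodromy matrix is the ordered product over one
period.

Forward sensitivities solve dS_j/dt = J(t) S_j + ∂f/∂k_j with initial
condition per kind:

* transient: S_j(0) = 0 (the initial state does not depend on k);
* forced-periodic: S_j(0) = (I − C(0,T))⁻¹ P_j, where P_j is the zero-IC
  particular response over one period — this is the unique periodic solution;
* autonomous-periodic: periodicity is degenerate (unit multiplier), so the
  periodicity defect and the differentiated phase anchor are solved together
  in a bordered system whose extra unknown is the period gradient dτ/dk_j.

Only *free* parameters get sensitivity columns; parameters listed in the
template's `fixed:` section (typically Hill exponents) are excluded from all
sensitivity outputs.

**Period rescaling.** With λ(k) = τ(k)/τ₀ (so the rescaled solution
ḡ(t,k) = g(λt,k) has parameter-independent period), the rescaled derivative
is ∂ḡ/∂k_j(t) = ∂g/∂k_j(t) + (t/τ)(dτ/dk_j) ġ(t).  Any other λ convention
differs by an additive multiple of ġ; this one makes the raw ↔ rescaled split
exactly complementary: raw = shape (rescaled) + period part, with
period part = −(t/τ)(dτ/dk_j) ġ(t).  The λ–ω fixture is the degenerate check:
its shape derivative with respect to ω vanishes identically because changing
ω only reparameterises time.

## Response theory

**Adjoint route to IRCs.** The periodic adjoint solution Z of Ż = −J(t)ᵀZ
with Z·f ≡ 1 is the left Floquet eigenvector of the unit multiplier
transported along the orbit.  It is computed from the monodromy matrix and
then propagated *backwards* in time (the adjoint's neutral direction is
non-expanding backwards, so the solve is stable).  One backward solve serves
all parameters:

    IRC_j(φ) = −Z(φ)·(∂f/∂k_j)(φ),      ∫₀^τ IRC_j dφ = dτ/dk_j.

Sign convention: the full-cycle integral *is* the period derivative, and a
pulse δk over a window shifts subsequent peak times (asymptotically, after
the transient Floquet modes decay) by +δk·(window integral).  Equivalently, a
positive windowed area means period lengthening / phase delay.  Trapezoid
quadrature is used for windowed integrals: on the uniform periodic grid it is
spectrally accurate for the (smooth, periodic) IRCs.

**Phase derivatives (entrained orbits).** Implicit differentiation of the
peak condition ġ_m(φ) = 0 gives

    ∂φ/∂k_j = −(∇ₓf_m·S_j(φ) + ∂f_m/∂k_j) / g̈_m(φ),

with g̈ computed analytically as (J·f + ∂f/∂t)_m — no second finite
differencing.  S_j at the (off-grid) event time is interpolated with a cubic
spline; flat extrema (g̈ ≈ 0) raise an error.

**Phase IRCs.** The per-phase curve is built by propagating the peak
condition backwards through one period with the resolvent
(I − C(t_e, t_e+τ))⁻¹ folded in: an impulse applied at phase φ recurs every
forcing cycle, and the resolvent sums the geometric series of echoes.  The
curve necessarily jumps at the event time (the impulse switches from acting
on this cycle's peak to the next one's); the direct dependence ∂f_m/∂k_j at
the event appears as a separate *point term*.  Curve values use the
advance-positive convention, so the permanent-perturbation phase derivative
equals −(signed area + point term) — an identity that holds to ~1e−7 because
the signed area is accumulated as an extra quadrature state of the backward
ODE solve rather than by trapezoid across the discontinuity.  The exact split
between curve and point term is a convention; only their sum and the
windowed areas away from the event are observable, and both are validated
against re-entrainment oracles.

## Global SVD layer

The derivative surfaces are flattened entity-major into M = ∂g/∂k (one row
per variable-or-composite and timepoint, one column per free parameter).
Numerical choices:

* rows are weighted by √(Δt_l) (trapezoid weights) so ‖δg‖² approximates the
  continuous L² norm and the spectrum is invariant under grid refinement;
  weighting is skipped for explicit timepoint selections (discrete
  observations), and can be disabled to reproduce the unweighted convention;
* the SVD sign convention makes each V column's largest-magnitude entry
  positive (ties → first index) so S matrices are reproducible;
* `log_params` multiplies column j by k_j (chain rule to ∂g/∂log k_j) —
  useful when parameter magnitudes span orders of magnitude;
* `relative` divides each entity's rows by its *time-mean* level, not the
  pointwise value, to avoid division near zero crossings;
* knockouts are modelled by setting the rate parameter to zero in that
  experiment's parameter vector; the parameter keeps its (now exactly zero)
  column so that experiments remain column-compatible for concatenation.
  A knocked-out oscillator generally has no cycle, so the knockout
  experiment's solution of interest is a transient — any solution kind can
  serve as an experiment.

The amplitude/phase decomposition uses R_m ∝ ġ_m on the grid (an
infinitesimal time translation) and A_m = the centred waveform
orthogonalised against R_m and normalised (an amplitude change); (α, β) are
orthogonal projections and the residual is orthogonal to both.  The
construction of A_m is one of several possible; it satisfies the
orthonormality contract exactly and reduces to the Fourier picture
(translation ∝ sin, amplitude ∝ cos) for sinusoidal cycles.

## Fixture models (the stated world)

* **lambda_omega** (ω = 2π): polar form ṙ = r(1−r²), θ̇ = ω.  Closed forms:
  τ = 2π/ω, non-trivial multiplier e^{−2τ}, Z = (−y, x)/ω on the cycle,
  IRC w.r.t. ω ≡ −1/ω, dτ/dω = −2π/ω².  Every analytic acceptance check
  traces back to these.
* **van_der_pol** (μ = 1): reference period 6.6632868593231 from
  high-accuracy integration.
* **goodwin**: a/(1+z^h) repression with h = 10 (fixed), unit production
  gains and equal decay rates 0.2 — standard textbook scales satisfying the
  secant condition (h > 8) for oscillation.  At these values τ ≈ 19.65 and
  the non-trivial multipliers are ≈ 0.63 and 1.2e−5; the slow mode means
  pulse-response oracles need ~25 cycles before the asymptotic phase shift
  is reached.
* **goodwin_forced**: the same loop with transcription multiplied by a 12:12
  square wave (period 24, levels 1.0/0.2).  The 0.2 night level keeps the
  loop alive while modulating strongly enough to entrain the ~19.65 h
  free-running period to 24 h (largest multiplier ≈ 0.6).
* **cascade**: linear three-stage chain with negative feedback r = 2 < 8
  (stable by the secant condition); the `stim` parameter switches 0 → 2.

These fixtures exercise every code path at desk scale but are small and
non-stiff; green tests establish correctness of the machinery, not
performance or robustness on stiff, high-dimensional models (e.g. realistic
clock models with ~100 parameters), where solver-method choice and the
conditioning of the resolvent in the phase-IRC construction would deserve
attention.

## Known limitations

* Backward adjoint propagation and the phase-IRC resolvent assume the
  non-unit Floquet multipliers are comfortably inside the unit circle;
  near-critical entrainment (multiplier → 1) degrades accuracy before the
  explicit singularity error triggers.
* Multiple coexisting attractors: the first cycle found from the supplied
  guess wins; no continuation or bifurcation tracking.
* Forcing profiles are piecewise constant; smoothly varying forcings must be
  written directly into the equations (where they are differentiated
  symbolically like everything else).
* SBML export covers unforced models (rate rules only, no events); SBML
  import is out of scope.
* Second-order sensitivities are not computed; all predictions are
  first-order and their validity range shrinks with the nonlinearity (the
  first-order prediction check observes ~1 % error at ‖δk‖ = 1e−3‖k‖ on the
  Goodwin cycle).
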