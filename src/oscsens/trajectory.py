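"""Computation of the solution of interest.

Three kinds of reference trajectory are supported:

* ``autonomous-periodic`` — an attracting limit cycle of an unforced
  oscillator, refined by Newton shooting on the periodic boundary-value
  problem with the period as an unknown and a phase anchor fixing the
  starting point at the peak of the first variable;
* ``forced-periodic`` — the entrained orbit of a periodically forced
  oscillator, a fixed point of the period-T return map found by Newton
  iteration with the monodromy matrix as Jacobian;
* ``transient`` — a stimulated trajectory started from the unstimulated
  equilibrium of a signalling system.

All integrations split the time span at forcing switch times so the
discontinuities never sit inside a solver step.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

from .exceptions import AnalysisError, SolverError
from .model import CompiledModel

__all__ = [
    "SolutionOfInterest",
    "PhaseEvent",
    "simulate",
    "find_limit_cycle_autonomous",
    "find_entrained_orbit",
    "find_signalling_solution",
    "detect_phase_events",
]

DEFAULT_RTOL = 1e-9
DEFAULT_ATOL = 1e-12
DEFAULT_GRID_POINTS = 241  # per period, for periodic solutions


class PiecewiseInterpolant:
    """Dense output stitched together from per-segment solver interpolants."""

    def __init__(self, segments):
        # segments: list of (t0, t1, scipy OdeSolution)
        self._segments = segments
        self.t_min = segments[0][0]
        self.t_max = segments[-1][1]

    def __call__(self, t):
        t = float(t)
        eps = 1e-9 * max(1.0, abs(self.t_max))
        if t < self.t_min - eps or t > self.t_max + eps:
            raise ValueError(f"time {t} outside [{self.t_min}, {self.t_max}]")
        for t0, t1, sol in self._segments:
            if t <= t1 or (t0, t1, sol) is self._segments[-1]:
                return np.asarray(sol(np.clip(t, t0, t1)), dtype=float)
        raise AssertionError("unreachable")


def integrate_segments(model: CompiledModel, fun, t0: float, t1: float, y0,
                       *, t_eval=None, rtol=DEFAULT_RTOL, atol=DEFAULT_ATOL,
                       method="DOP853", dense=False):
    """Integrate dy/dt = fun(t, y) over [t0, t1], splitting at forcing switches.

    Returns ``(y_eval, interp)`` where ``y_eval`` has one row per requested
    time (None if t_eval is None) and ``interp`` is a PiecewiseInterpolant
    (None unless dense).
    """
    breaks = model.breakpoints(t0, t1)
    edges = np.concatenate(([t0], breaks, [t1]))
    t_eval = None if t_eval is None else np.asarray(t_eval, dtype=float)
    y = np.asarray(y0, dtype=float)
    rows = {} if t_eval is not None else None
    segments = []
    for a, b in zip(edges[:-1], edges[1:]):
        want = None
        if t_eval is not None:
            mask = (t_eval >= a - 1e-12) & (t_eval <= b + 1e-12)
            want = np.clip(t_eval[mask], a, b)
        res = solve_ivp(fun, (a, b), y, method=method, rtol=rtol, atol=atol,
                        dense_output=True, t_eval=None)
        if not res.success:
            raise SolverError(f"integration failed on [{a}, {b}] at t="
                              f"{res.t[-1] if len(res.t) else a}: {res.message}")
        if want is not None and len(want):
            vals = res.sol(want)
            for tt, col in zip(t_eval[mask], np.atleast_2d(vals.T)):
                rows[float(tt)] = col
        segments.append((a, b, res.sol))
        y = res.y[:, -1]
    y_eval = None
    if t_eval is not None:
        y_eval = np.array([rows[float(tt)] for tt in t_eval])
    interp = PiecewiseInterpolant(segments) if dense else None
    return y, y_eval, interp


@dataclass
class SolutionOfInterest:
    """A reference trajectory g(t, k) sampled on a fine time grid."""

    kind: str  # "autonomous-periodic" | "forced-periodic" | "transient"
    grid: np.ndarray
    states: np.ndarray  # N x n
    period: float | None
    params: np.ndarray
    initial_state: np.ndarray
    residual: float
    model: CompiledModel = field(repr=False, default=None)
    interpolant: PiecewiseInterpolant = field(repr=False, default=None)
    rtol: float = DEFAULT_RTOL
    atol: float = DEFAULT_ATOL
    method: str = "DOP853"

    def __call__(self, t: float) -> np.ndarray:
        """Dense state at time t within the solved span."""
        if self.interpolant is None:
            raise AnalysisError("solution carries no dense interpolant")
        return self.interpolant(t)

    @property
    def n(self) -> int:
        return self.states.shape[1]

    @property
    def is_periodic(self) -> bool:
        return self.kind in ("autonomous-periodic", "forced-periodic")

    def state_derivatives(self) -> np.ndarray:
        """dx/dt = f(t, g(t), k) evaluated on the grid (N x n)."""
        return np.array([self.model.rhs_eval(t, x, self.params)
                         for t, x in zip(self.grid, self.states)])


def _uniform_grid(t0: float, t1: float, grid_density=None, n_points=None) -> np.ndarray:
    if n_points is None:
        density = 32.0 if grid_density is None else float(grid_density)
        if density < 2.0:
            raise ValueError("grid_density must be at least 2 points per unit time")
        n_points = max(2, int(round(density * (t1 - t0))) + 1)
    return np.linspace(t0, t1, n_points)


def simulate(model: CompiledModel, params, x0, t_span, grid_density=None,
             *, n_points=None, rtol=DEFAULT_RTOL, atol=DEFAULT_ATOL,
             method="DOP853") -> SolutionOfInterest:
    """Plain initial-value simulation; returns a transient solution of interest."""
    k = model.param_vector(params)
    t0, t1 = float(t_span[0]), float(t_span[1])
    if not np.isfinite([t0, t1]).all() or t1 <= t0:
        raise ValueError("t_span must be finite with t1 > t0")
    grid = _uniform_grid(t0, t1, grid_density, n_points)
    x0 = np.asarray(x0, dtype=float)
    fun = lambda t, y: model.rhs_eval(t, y, k)
    _, states, interp = integrate_segments(model, fun, t0, t1, x0, t_eval=grid,
                                           rtol=rtol, atol=atol, method=method,
                                           dense=True)
    return SolutionOfInterest(kind="transient", grid=grid, states=states,
                              period=None, params=k, initial_state=x0,
                              residual=0.0, model=model, interpolant=interp,
                              rtol=rtol, atol=atol, method=method)


def _flow_with_stm(model: CompiledModel, k, x0, t0, t1, rtol, atol, method):
    """Integrate the flow together with its state-transition matrix."""
    n = model.n
    y0 = np.concatenate([x0, np.eye(n).ravel()])

    def fun(t, y):
        x = y[:n]
        phi = y[n:].reshape(n, n)
        f = model.rhs_eval(t, x, k)
        J = model.jac_x_eval(t, x, k)
        return np.concatenate([f, (J @ phi).ravel()])

    yT, _, _ = integrate_segments(model, fun, t0, t1, y0, rtol=rtol, atol=atol,
                                  method=method)
    return yT[:n], yT[n:].reshape(n, n)


def _estimate_period(times: np.ndarray, series: np.ndarray) -> tuple[float, float]:
    """Estimate oscillation period and the time of the last peak from samples."""
    peaks = []
    for i in range(1, len(series) - 1):
        if series[i] >= series[i - 1] and series[i] > series[i + 1]:
            # parabolic refinement of the peak time
            denom = series[i - 1] - 2 * series[i] + series[i + 1]
            shift = 0.0 if denom == 0 else 0.5 * (series[i - 1] - series[i + 1]) / denom
            dt = times[i + 1] - times[i]
            peaks.append(times[i] + shift * dt)
    if len(peaks) < 3:
        raise SolverError("could not estimate a period: fewer than three peaks "
                          "found in the pre-integration window (is the system "
                          "oscillating? try a longer pre-integration)")
    gaps = np.diff(peaks[-6:])
    return float(np.mean(gaps)), float(peaks[-1])


def find_limit_cycle_autonomous(model: CompiledModel, params, guess_state,
                                guess_period=None, *, pre_periods=20,
                                grid_points=DEFAULT_GRID_POINTS,
                                rtol=DEFAULT_RTOL, atol=DEFAULT_ATOL,
                                method="DOP853", tol=1e-10, max_iter=30,
                                amplitude_threshold=1e-6) -> SolutionOfInterest:
    """Locate an attracting limit cycle by pre-integration + Newton shooting.

    The periodic BVP has unknowns (x0, tau) and equations
    ``x(tau; x0) - x0 = 0`` plus the phase anchor ``f_1(x0) = 0`` (the orbit
    starts at the peak of the first variable).
    """
    if model.spec.forcings and model.forcing_period is not None:
        raise AnalysisError("model is forced; use find_entrained_orbit")
    k = model.param_vector(params)
    x = np.asarray(guess_state, dtype=float)

    if pre_periods and pre_periods >= 1:
        # --- pre-integrate onto the attractor, line up period / anchor guesses
        horizon = pre_periods * (guess_period if guess_period else 10.0)
        dens = max(40.0 / (guess_period if guess_period else 10.0), 2.0)
        pre = simulate(model, k, x, (0.0, horizon), grid_density=dens,
                       rtol=rtol, atol=atol, method=method)
        tail = pre.grid >= 0.5 * horizon
        series = pre.states[tail, 0]
        if series.max() - series.min() < amplitude_threshold:
            raise SolverError("trajectory spirals to an equilibrium: oscillation "
                              "amplitude below threshold after pre-integration")
        tau, t_peak = _estimate_period(pre.grid[tail], series)
        if guess_period is not None:
            # trust the caller if the estimate is wildly off (multiphasic variables)
            if not (0.5 * guess_period < tau < 2.0 * guess_period):
                tau = float(guess_period)
        x0 = pre(min(t_peak, pre.grid[-1]))
    else:
        # warm restart: refine straight from the supplied guesses
        if guess_period is None:
            raise ValueError("guess_period is required when pre_periods == 0")
        tau = float(guess_period)
        x0 = x

    # --- Newton iteration on the bordered shooting system
    n = model.n
    residual = np.inf
    for _ in range(max_iter):
        xT, phi = _flow_with_stm(model, k, x0, 0.0, tau, rtol, atol, method)
        r = xT - x0
        anchor = model.rhs_eval(0.0, x0, k)[0]
        residual = max(np.abs(r).max(), abs(anchor))
        if residual <= tol:
            break
        A = np.zeros((n + 1, n + 1))
        A[:n, :n] = phi - np.eye(n)
        A[:n, n] = model.rhs_eval(tau, xT, k)
        A[n, :n] = model.jac_x_eval(0.0, x0, k)[0]
        rhs = -np.concatenate([r, [anchor]])
        try:
            delta = np.linalg.solve(A, rhs)
        except np.linalg.LinAlgError as exc:
            raise SolverError(f"Newton system singular: {exc}; try a longer "
                              "pre-integration") from exc
        x0 = x0 + delta[:n]
        tau = tau + delta[n]
        if tau <= 0:
            raise SolverError("period went non-positive during Newton; try a "
                              "longer pre-integration")
    if residual > 1e-8:
        raise SolverError(f"periodic BVP did not converge (residual {residual:.3e}); "
                          "try a longer pre-integration")

    # make sure the anchor is a peak, not a trough
    if model.second_derivative(0.0, x0, k)[0] > 0:
        half, _ = _flow_with_stm(model, k, x0, 0.0, tau / 2.0, rtol, atol, method)
        return find_limit_cycle_autonomous(model, k, half, tau,
                                           pre_periods=2, grid_points=grid_points,
                                           rtol=rtol, atol=atol, method=method,
                                           tol=tol, max_iter=max_iter)

    grid = np.linspace(0.0, tau, grid_points)
    fun = lambda t, y: model.rhs_eval(t, y, k)
    _, states, interp = integrate_segments(model, fun, 0.0, tau, x0, t_eval=grid,
                                           rtol=rtol, atol=atol, method=method,
                                           dense=True)
    return SolutionOfInterest(kind="autonomous-periodic", grid=grid, states=states,
                              period=float(tau), params=k, initial_state=x0,
                              residual=float(residual), model=model,
                              interpolant=interp, rtol=rtol, atol=atol,
                              method=method)


def find_entrained_orbit(model: CompiledModel, params, forcing_period=None, *,
                         x0_guess=None, pre_periods=20,
                         grid_points=DEFAULT_GRID_POINTS, rtol=DEFAULT_RTOL,
                         atol=DEFAULT_ATOL, method="DOP853", tol=1e-11,
                         max_iter=30) -> SolutionOfInterest:
    """Entrained periodic orbit of a forced model: fixed point of the return map."""
    model_period = model.forcing_period
    if model_period is None:
        raise AnalysisError("model has no periodic forcing; use "
                            "find_limit_cycle_autonomous or simulate")
    T = float(forcing_period) if forcing_period is not None else model_period
    if abs(T - model_period) > 1e-9 * model_period:
        raise AnalysisError(f"forcing_period {T} does not match the model's "
                            f"forcing period {model_period}")
    k = model.param_vector(params)
    if x0_guess is None:
        x0 = np.ones(model.n)
    else:
        x0 = np.asarray(x0_guess, dtype=float)
    if pre_periods:
        pre = simulate(model, k, x0, (0.0, pre_periods * T),
                       n_points=max(2, 4 * int(pre_periods)),
                       rtol=rtol, atol=atol, method=method)
        x0 = pre.states[-1]

    residual = np.inf
    phi = None
    for _ in range(max_iter):
        xT, phi = _flow_with_stm(model, k, x0, 0.0, T, rtol, atol, method)
        r = xT - x0
        residual = np.abs(r).max()
        if residual <= tol:
            break
        x0 = x0 + np.linalg.solve(np.eye(model.n) - phi, r)
    multipliers = np.linalg.eigvals(phi)
    if np.abs(multipliers).max() >= 1.0:
        raise SolverError("return map has a Floquet multiplier of modulus >= 1 "
                          f"(multipliers {np.round(multipliers, 6)}); the system "
                          "is not entrained to a stable orbit")
    if residual > 1e-9:
        raise SolverError(f"entrained orbit did not converge (defect {residual:.3e})")

    grid = np.linspace(0.0, T, grid_points)
    fun = lambda t, y: model.rhs_eval(t, y, k)
    _, states, interp = integrate_segments(model, fun, 0.0, T, x0, t_eval=grid,
                                           rtol=rtol, atol=atol, method=method,
                                           dense=True)
    return SolutionOfInterest(kind="forced-periodic", grid=grid, states=states,
                              period=T, params=k, initial_state=x0,
                              residual=float(residual), model=model,
                              interpolant=interp, rtol=rtol, atol=atol,
                              method=method)


def find_signalling_solution(model: CompiledModel, params_unstimulated,
                             params_stimulated, T, *, x0_guess=None,
                             pre_time=200.0, grid_density=None, n_points=None,
                             rtol=DEFAULT_RTOL, atol=DEFAULT_ATOL,
                             method="DOP853") -> SolutionOfInterest:
    """Stimulated transient from the unstimulated stable equilibrium.

    The equilibrium is seeded by a long unstimulated integration and polished
    by damped Newton on f(x) = 0; it must be linearly stable.
    """
    k0 = model.param_vector(params_unstimulated)
    k1 = model.param_vector(params_stimulated)
    x = np.ones(model.n) if x0_guess is None else np.asarray(x0_guess, dtype=float)
    try:
        pre = simulate(model, k0, x, (0.0, pre_time), grid_density=2.0,
                       rtol=1e-8, atol=1e-10, method=method)
    except SolverError as exc:
        raise SolverError(f"no equilibrium found (pre-integration failed: {exc})")
    x = pre.states[-1]

    for _ in range(60):
        f = model.rhs_eval(0.0, x, k0)
        if np.abs(f).max() <= 1e-12:
            break
        J = model.jac_x_eval(0.0, x, k0)
        try:
            step = np.linalg.solve(J, -f)
        except np.linalg.LinAlgError as exc:
            raise SolverError(f"no equilibrium found (singular Jacobian: {exc})")
        lam = 1.0
        norm0 = np.abs(f).max()
        while lam > 1e-6:
            trial = x + lam * step
            if np.abs(model.rhs_eval(0.0, trial, k0)).max() < norm0:
                break
            lam *= 0.5
        x = x + lam * step
    x0 = x
    f0 = np.abs(model.rhs_eval(0.0, x0, k0)).max()
    if f0 > 1e-10:
        raise SolverError(f"no equilibrium found (residual {f0:.3e} after Newton)")
    eigs = np.linalg.eigvals(model.jac_x_eval(0.0, x0, k0))
    if eigs.real.max() >= 0:
        raise SolverError("unstimulated equilibrium is not stable "
                          f"(leading eigenvalue {eigs.real.max():.3e})")
    sol = simulate(model, k1, x0, (0.0, float(T)), grid_density=grid_density,
                   n_points=n_points, rtol=rtol, atol=atol, method=method)
    sol.residual = float(f0)
    return sol


@dataclass(frozen=True)
class PhaseEvent:
    """A peak or trough of one variable on a periodic solution."""

    variable_index: int
    kind: str  # "peak" | "trough"
    time: float
    value: float


def detect_phase_events(solution: SolutionOfInterest, variable_index: int,
                        *, tol=1e-8) -> list[PhaseEvent]:
    """All extrema of one variable over one period, ordered by time.

    Extremum times are bracketed by sign changes of the interpolated
    derivative and refined with a root solve of ``f_m(t, g(t)) = 0``;
    classification uses the analytic second derivative.
    """
    if not solution.is_periodic:
        raise AnalysisError("phase events are defined for periodic solutions only")
    m = int(variable_index)
    model, k = solution.model, solution.params
    grid, states = solution.grid, solution.states
    if states[:, m].max() - states[:, m].min() < 1e-12:
        return []
    dots = solution.state_derivatives()[:, m]
    scale = np.abs(dots).max()
    if scale == 0:
        return []

    from scipy.optimize import brentq

    def dot_m(t):
        return model.rhs_eval(t, solution(t), k)[m]

    events = []
    times_found = []

    def push(t_ev):
        t_ev = t_ev % solution.period
        for prev in times_found:
            if abs(prev - t_ev) < 1e-6 * solution.period:
                return
        x_ev = solution(min(t_ev, grid[-1]))
        acc = model.second_derivative(t_ev, x_ev, k)[m]
        kind = "peak" if acc < 0 else "trough"
        times_found.append(t_ev)
        events.append(PhaseEvent(variable_index=m, kind=kind, time=float(t_ev),
                                 value=float(x_ev[m])))

    if abs(dots[0]) <= tol * scale:
        push(grid[0])
    for i in range(len(grid) - 1):
        a, b = dots[i], dots[i + 1]
        if abs(a) <= tol * scale or abs(b) <= tol * scale:
            if abs(b) <= tol * scale and i + 1 < len(grid) - 1:
                push(grid[i + 1])
            continue
        if a * b < 0:
            t_ev = brentq(dot_m, grid[i], grid[i + 1], xtol=1e-12)
            push(t_ev)
    events.sort(key=lambda e: e.time)
    return events
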