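"""Period derivatives, infinitesimal response curves and phase machinery.

For a free-running oscillator the periodic adjoint solution Z(t) of
``dZ/dt = -J(t)^T Z`` with normalisation ``Z·f = 1`` (the left Floquet
eigenvector of the unit multiplier, transported along the orbit) gives the
infinitesimal response curve of the period for every parameter in a single
backward solve:

    IRC_j(phi) = -Z(phi) · (∂f/∂k_j)(phi),     ∫₀^τ IRC_j = dτ/dk_j.

A temporary parameter change over a window [phi1, phi2] changes the output
by ``δQ = Σ_j δk_j ∫_{phi1}^{phi2} IRC_j dphi`` to first order.

For an entrained forced oscillator the period is pinned by the forcing and
the observables are event (peak/trough) times.  Phase derivatives come from
implicit differentiation of the peak condition ``ġ_m(phi) = 0``; the phase
IRC resolves that total derivative into a per-phase curve (with a jump at
the event) plus a point term from the direct parameter dependence at the
event.  Curve values use the advance-positive convention: a positive value
means an infinitesimal perturbation at that phase moves the peak earlier,
so ∂phi/∂k = -(signed area + point term).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.interpolate import CubicSpline

from .exceptions import AnalysisError, SolverError
from .model import CompiledModel
from .trajectory import PhaseEvent, SolutionOfInterest, detect_phase_events
from .variational import SensitivityField, VariationalData, fundamental_matrix

__all__ = [
    "AdjointSolution",
    "ResponseCurve",
    "PhaseIRC",
    "adjoint_solution",
    "irc",
    "window_response",
    "period_derivatives",
    "phase_derivatives",
    "phase_irc",
    "classical_coefficient",
    "rank_parameters",
]


@dataclass
class AdjointSolution:
    """Periodic adjoint solution with Z·f = 1 on the grid."""

    grid: np.ndarray
    Z: np.ndarray  # (N, n)
    solution: SolutionOfInterest = field(repr=False, default=None)


def _wrap_time(t: float, period: float) -> float:
    tau = t % period
    return tau


def _backward_adjoint(model: CompiledModel, solution: SolutionOfInterest,
                      t_end: float, y_end: np.ndarray, length: float,
                      psi_eval: np.ndarray, extra_quadrature: bool):
    """Integrate y' = -J^T y backwards from t_end over ``length`` time units.

    Works in the forward variable psi = t_end - t; optionally accumulates
    the quadratures q_j(psi) = ∫ y·B_j dphi for every free parameter.
    The trajectory is accessed periodically (wrapped modulo the period).
    """
    n = model.n
    free = model.free_indices
    nf = len(free)
    k = solution.params
    period = solution.period

    def state_at(t):
        return solution(_wrap_time(t, period))

    def fun(psi, y):
        t = t_end - psi
        x = state_at(t)
        J = model.jac_x_eval(t, x, k)
        dy = J.T @ y[:n]
        if not extra_quadrature:
            return dy
        B = model.jac_k_eval(t, x, k)[:, free]
        return np.concatenate([dy, y[:n] @ B])

    y0 = y_end if not extra_quadrature else np.concatenate([y_end, np.zeros(nf)])

    # segment at forcing switch times crossed by t = t_end - psi
    switches = []
    if model.switch_times and period:
        fp = model.forcing_period
        import math
        j0 = math.floor((t_end - length) / fp) - 1
        j1 = math.ceil(t_end / fp) + 1
        for j in range(j0, j1 + 1):
            for off in model.switch_times:
                t_sw = j * fp + off
                psi_sw = t_end - t_sw
                if 1e-12 < psi_sw < length - 1e-12:
                    switches.append(psi_sw)
    edges = np.concatenate(([0.0], np.sort(switches), [length]))

    psi_eval = np.asarray(psi_eval, dtype=float)
    out = np.empty((len(psi_eval), len(y0)))
    y = np.asarray(y0, dtype=float)
    for a, b in zip(edges[:-1], edges[1:]):
        res = solve_ivp(fun, (a, b), y, method=solution.method,
                        rtol=min(solution.rtol, 1e-10), atol=solution.atol,
                        dense_output=True)
        if not res.success:
            raise SolverError(f"adjoint solve failed on psi in [{a}, {b}]: "
                              f"{res.message}")
        mask = (psi_eval >= a - 1e-12) & (psi_eval <= b + 1e-12)
        if mask.any():
            out[mask] = res.sol(np.clip(psi_eval[mask], a, b)).T
        y = res.y[:, -1]
    return out, y


def adjoint_solution(model: CompiledModel, solution: SolutionOfInterest,
                     data: VariationalData) -> AdjointSolution:
    """The unique periodic adjoint solution with Z·f = 1 everywhere."""
    if solution.kind != "autonomous-periodic":
        raise AnalysisError("the period adjoint is defined for autonomous "
                            "limit cycles only")
    M = data.monodromy_matrix
    lams, vecs = np.linalg.eig(M.T)
    order = np.argsort(np.abs(lams - 1.0))
    if abs(lams[order[0]] - 1.0) > 1e-4:
        raise SolverError(f"monodromy has no unit Floquet multiplier "
                          f"(closest: {lams[order[0]]:.6g})")
    if len(lams) > 1 and abs(lams[order[1]] - 1.0) < 1e-6:
        raise SolverError("unit Floquet multiplier is degenerate "
                          "(multiplicity > 1); the adjoint is not unique")
    v = vecs[:, order[0]]
    if np.abs(v.imag).max() > 1e-8 * np.abs(v).max():
        raise SolverError("unit-multiplier left eigenvector is not real")
    v = v.real
    f0 = model.rhs_eval(0.0, solution.initial_state, solution.params)
    scale = v @ f0
    if abs(scale) < 1e-12:
        raise SolverError("left eigenvector orthogonal to the flow direction")
    v = v / scale

    tau = solution.period
    psi_eval = tau - solution.grid  # Z(t_l) at psi = tau - t_l
    order_idx = np.argsort(psi_eval)
    Z_rows, _ = _backward_adjoint(model, solution, t_end=tau, y_end=v,
                                  length=tau, psi_eval=psi_eval[order_idx],
                                  extra_quadrature=False)
    Z = np.empty_like(Z_rows)
    Z[order_idx] = Z_rows
    return AdjointSolution(grid=solution.grid, Z=Z, solution=solution)


@dataclass
class ResponseCurve:
    """IRC of one parameter for one scalar observable over a full cycle."""

    parameter: str
    observable: str  # "period"
    phi: np.ndarray
    values: np.ndarray
    signed_area: float
    param_value: float
    period: float


def irc(model: CompiledModel, solution: SolutionOfInterest,
        adjoint: AdjointSolution) -> list[ResponseCurve]:
    """Period IRCs for every free parameter: -Z(phi)·(∂f/∂k_j)(phi)."""
    free = model.free_indices
    k = solution.params
    B = np.array([model.jac_k_eval(t, x, k)[:, free]
                  for t, x in zip(solution.grid, solution.states)])  # (N, n, nf)
    vals = -np.einsum("ln,lnj->lj", adjoint.Z, B)
    curves = []
    for j, name in enumerate(model.free_parameters):
        area = float(np.trapezoid(vals[:, j], solution.grid))
        curves.append(ResponseCurve(parameter=name, observable="period",
                                    phi=solution.grid, values=vals[:, j],
                                    signed_area=area,
                                    param_value=float(k[model.spec.parameters.index(name)]),
                                    period=solution.period))
    return curves


def window_response(curve: ResponseCurve, phi1: float, phi2: float,
                    delta_k: float) -> float:
    """First-order output change for δk applied only during [phi1, phi2]."""
    tau = curve.phi[-1]
    if not (0.0 <= phi1 <= phi2 <= tau + 1e-12):
        raise ValueError(f"window [{phi1}, {phi2}] outside [0, {tau}]")
    if phi1 == phi2:
        return 0.0
    inside = (curve.phi > phi1) & (curve.phi < phi2)
    xs = np.concatenate(([phi1], curve.phi[inside], [phi2]))
    ys = np.interp(xs, curve.phi, curve.values)
    return float(delta_k * np.trapezoid(ys, xs))


def period_derivatives(ircs: list[ResponseCurve], *, scale="absolute",
                       sort=None) -> pd.Series:
    """dτ/dk_j as the full-cycle signed areas of the period IRCs.

    ``scale="relative"`` reports (k_j/τ)·dτ/dk_j; ``sort`` may be "value",
    "abs" or "name".
    """
    if not ircs:
        raise AnalysisError("no IRC curves supplied")
    for c in ircs:
        if c.observable != "period":
            raise AnalysisError("period derivatives need period IRCs (the "
                                "notion is only defined for unforced oscillators)")
    vals = {c.parameter: c.signed_area for c in ircs}
    if scale == "relative":
        vals = {c.parameter: c.signed_area * c.param_value / c.period for c in ircs}
    elif scale != "absolute":
        raise ValueError(f"unknown scale {scale!r}")
    out = pd.Series(vals, name=f"dtau_dk ({scale})")
    if sort == "value":
        out = out.sort_values(ascending=False)
    elif sort == "abs":
        out = out.reindex(out.abs().sort_values(ascending=False).index)
    elif sort == "name":
        out = out.sort_index()
    elif sort is not None:
        raise ValueError(f"unknown sort {sort!r}")
    return out


def _event_curvature(model: CompiledModel, solution: SolutionOfInterest,
                     event: PhaseEvent) -> float:
    x_e = solution(event.time)
    acc = model.second_derivative(event.time, x_e, solution.params)[event.variable_index]
    f_all = solution.state_derivatives()[:, event.variable_index]
    scale = np.abs(f_all).max() / max(solution.period, 1e-12)
    if abs(acc) < 1e-8 * max(scale, 1e-12):
        raise AnalysisError(f"flat extremum at t={event.time}: second "
                            "derivative is numerically zero")
    return float(acc)


def phase_derivatives(model: CompiledModel, forced_solution: SolutionOfInterest,
                      field: SensitivityField, event: PhaseEvent, *,
                      log_params=False) -> pd.Series:
    """∂phi/∂k_j for an event on an entrained orbit, by implicit differentiation.

    Differentiating the peak condition ġ_m(phi) = 0 gives
    ``∂phi/∂k_j = -(∇_x f_m · S_j(phi) + ∂f_m/∂k_j) / g̈_m(phi)``.
    """
    if forced_solution.kind != "forced-periodic":
        raise AnalysisError("phase derivatives apply to entrained forced "
                            "oscillators only")
    m = event.variable_index
    t_e = event.time
    k = forced_solution.params
    x_e = forced_solution(t_e)
    acc = _event_curvature(model, forced_solution, event)
    S_e = CubicSpline(field.grid, field.raw, axis=0)(t_e)  # (n, nf)
    grad_x = model.jac_x_eval(t_e, x_e, k)[m]
    dfdk = model.jac_k_eval(t_e, x_e, k)[m, model.free_indices]
    num = grad_x @ S_e + dfdk
    vals = -num / acc
    if log_params:
        kfree = k[model.free_indices]
        vals = vals * kfree
    return pd.Series(vals, index=list(field.param_names),
                     name=f"dphi_dk[{model.spec.variables[m]} {event.kind} "
                          f"@ {t_e:.4g}]")


@dataclass
class PhaseIRC:
    """Phase response of one event to impulsive parameter perturbations.

    ``curve`` uses the advance-positive convention; it has a jump at the
    event time.  ``signed_area`` is computed by ODE quadrature during the
    backward propagation (trapezoid on the plotting grid is not accurate
    across the jump).  The permanent-perturbation phase derivative is
    ``-(signed_area + point_term)``.
    """

    event: PhaseEvent
    parameter: str
    phi: np.ndarray
    curve: np.ndarray
    point_term: float
    signed_area: float
    total_phase_derivative: float


def phase_irc(model: CompiledModel, forced_solution: SolutionOfInterest,
              data: VariationalData, event: PhaseEvent,
              parameter: str | None = None):
    """Phase IRC(s) of an event for one (or all) free parameters.

    An impulse δk·dphi applied at phase phi displaces the entrained orbit;
    propagating the displacement to the event through the resolvent
    (I - C(t_e, t_e+τ))⁻¹ (the perturbation recurs every cycle) and through
    the peak condition yields the curve; the direct ∂f_m/∂k_j dependence at
    the event gives the point term.
    """
    if forced_solution.kind != "forced-periodic":
        raise AnalysisError("phase IRCs apply to entrained forced oscillators only")
    tau = forced_solution.period
    t_e = event.time
    if not (0.0 <= t_e <= tau):
        raise AnalysisError("event does not lie on this solution")
    m = event.variable_index
    k = forced_solution.params
    free = model.free_indices
    n = model.n

    # C(0, t_e): composed grid steps plus the partial step up to t_e
    grid = data.grid
    i_lo = int(np.searchsorted(grid, t_e + 1e-12) - 1)
    i_lo = max(0, min(i_lo, len(grid) - 1))
    C0 = fundamental_matrix(data, grid[0], grid[i_lo])
    if t_e > grid[i_lo] + 1e-12:
        from .trajectory import integrate_segments

        def fun(t, y):
            x = forced_solution(t)
            J = model.jac_x_eval(t, x, k)
            return (J @ y.reshape(n, n)).ravel()

        yT, _, _ = integrate_segments(model, fun, grid[i_lo], t_e,
                                      np.eye(n).ravel(), rtol=forced_solution.rtol,
                                      atol=forced_solution.atol,
                                      method=forced_solution.method)
        C0 = yT.reshape(n, n) @ C0
    M = data.monodromy_matrix
    M_e = C0 @ M @ np.linalg.inv(C0)

    x_e = forced_solution(t_e)
    acc = _event_curvature(model, forced_solution, event)
    u = model.jac_x_eval(t_e, x_e, k)[m]
    w = np.linalg.solve(np.eye(n) - M_e.T, u)

    # backward propagation of w over one period with per-parameter quadrature
    psi_grid = np.where(forced_solution.grid <= t_e + 1e-12,
                        t_e - forced_solution.grid,
                        t_e + tau - forced_solution.grid)
    order = np.argsort(psi_grid)
    rows, y_final = _backward_adjoint(model, forced_solution, t_end=t_e,
                                      y_end=w, length=tau,
                                      psi_eval=psi_grid[order],
                                      extra_quadrature=True)
    Y = np.empty_like(rows)
    Y[order] = rows
    y_part, q_total = Y[:, :n], y_final[n:]

    B = np.array([model.jac_k_eval(t, x, k)[:, free]
                  for t, x in zip(forced_solution.grid, forced_solution.states)])
    curves = np.einsum("ln,lnj->lj", y_part, B) / acc  # advance convention
    areas = q_total / acc
    points = model.jac_k_eval(t_e, x_e, k)[m, free] / acc

    out = []
    for j, name in enumerate(model.free_parameters):
        out.append(PhaseIRC(event=event, parameter=name,
                            phi=forced_solution.grid, curve=curves[:, j],
                            point_term=float(points[j]),
                            signed_area=float(areas[j]),
                            total_phase_derivative=float(-(areas[j] + points[j]))))
    if parameter is None:
        return out
    for p in out:
        if p.parameter == parameter:
            return p
    raise KeyError(f"parameter {parameter!r} is not a free parameter")


def rank_parameters(curves, by="area") -> list[str]:
    """Order parameters by their response curves.

    ``by`` is "area" (|signed area|), "max_advance" (largest positive curve
    value) or "max_delay" (most negative curve value).
    """
    def score(c):
        vals = c.values if isinstance(c, ResponseCurve) else c.curve
        area = c.signed_area
        if by == "area":
            return abs(area)
        if by == "max_advance":
            return float(np.max(vals))
        if by == "max_delay":
            return float(-np.min(vals))
        raise ValueError(f"unknown ranking {by!r}")

    return [c.parameter for c in sorted(curves, key=score, reverse=True)]


def classical_coefficient(observable, field: SensitivityField,
                          solution: SolutionOfInterest) -> pd.Series:
    """Classical sensitivity coefficients C^Q_j for a scalar observable Q.

    ``observable`` is a tuple: ``("value", m, t_star)``, ``("amplitude", m)``,
    ``("period",)`` or ``("phase", event)``.
    """
    model = solution.model
    names = list(field.param_names)
    kind = observable[0]
    if kind == "value":
        _, m, t_star = observable
        S = CubicSpline(field.grid, field.raw, axis=0)(float(t_star))
        return pd.Series(S[int(m)], index=names, name=f"C[value x{m}@{t_star}]")
    if kind == "amplitude":
        m = int(observable[1])
        events = detect_phase_events(solution, m)
        peaks = [e for e in events if e.kind == "peak"]
        troughs = [e for e in events if e.kind == "trough"]
        if not peaks or not troughs:
            return pd.Series(np.zeros(len(names)), index=names,
                             name=f"C[amplitude x{m}]")
        peak = max(peaks, key=lambda e: e.value)
        trough = min(troughs, key=lambda e: e.value)
        spl = CubicSpline(field.grid, field.raw, axis=0)
        C = spl(peak.time)[m] - spl(trough.time)[m]
        return pd.Series(C, index=names, name=f"C[amplitude x{m}]")
    if kind == "period":
        if field.period_gradient is None:
            raise AnalysisError("period observable needs an autonomous cycle "
                                "with its period gradient")
        return pd.Series(field.period_gradient, index=names, name="C[period]")
    if kind == "phase":
        event = observable[1]
        return phase_derivatives(model, solution, field, event)
    raise AnalysisError(f"unknown observable {observable!r}")
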