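"""Variational equation, fundamental matrices and solution derivatives.

Along the solution of interest the linearised flow obeys
``dPhi/dt = J(t) Phi`` with ``J = ∂f/∂x``.  We store one state-transition
matrix per grid interval and compose them on demand into fundamental
matrices ``C(s, t)``; the product over a full period is the monodromy
matrix whose eigenvalues are the Floquet multipliers.

Solution derivatives ``∂g/∂k_j`` solve the forward sensitivity system
``dS_j/dt = J(t) S_j + ∂f/∂k_j`` with an initial condition that encodes how
the solution of interest is pinned down:

* transient — fixed initial state, so ``S_j(0) = 0``;
* forced-periodic — periodicity ``S_j(T) = S_j(0)`` gives
  ``S_j(0) = (I - C(0,T))^{-1} P_j`` with ``P_j`` the zero-IC particular
  response over one period;
* autonomous-periodic — the unit Floquet multiplier makes ``I - C(0,T)``
  singular, so periodicity is combined with the phase-anchor condition in a
  bordered linear solve that simultaneously yields the period gradient
  ``dτ/dk``.

The period-rescaled derivative subtracts the secular drift:
``∂ḡ/∂k_j(t) = ∂g/∂k_j(t) + (t/τ)(dτ/dk_j) ġ(t)`` (convention
λ(k) = τ(k)/τ₀, so the rescaled solution has fixed period).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import AnalysisError, SolverError
from .model import CompiledModel
from .trajectory import SolutionOfInterest, integrate_segments

__all__ = [
    "VariationalData",
    "SensitivityField",
    "compute_step_matrices",
    "fundamental_matrix",
    "monodromy",
    "solution_derivatives",
    "rescale_derivatives",
    "finite_difference_derivatives",
]

LAMBDA_CONVENTION = ("lambda(k) = tau(k)/tau0: rescaled derivative = raw + "
                     "(t/tau) * (dtau/dk_j) * dg/dt, periodic for cycles")


@dataclass
class VariationalData:
    """Per-interval state-transition matrices along a solution."""

    grid: np.ndarray
    step_matrices: np.ndarray  # (N-1, n, n): Phi(t_l -> t_{l+1})
    solution_kind: str
    monodromy_matrix: np.ndarray | None = None

    @property
    def n(self) -> int:
        return self.step_matrices.shape[1]


def compute_step_matrices(model: CompiledModel, solution: SolutionOfInterest,
                          *, rtol=None, atol=None) -> VariationalData:
    """Solve dPhi/dt = J(t)Phi with Phi = I restarted on every grid interval."""
    rtol = solution.rtol if rtol is None else rtol
    atol = solution.atol if atol is None else atol
    k = solution.params
    n = model.n
    grid = solution.grid
    steps = np.empty((len(grid) - 1, n, n))
    eye = np.eye(n)
    for l in range(len(grid) - 1):
        x_l = solution.states[l]
        y0 = np.concatenate([x_l, eye.ravel()])

        def fun(t, y):
            x = y[:n]
            phi = y[n:].reshape(n, n)
            f = model.rhs_eval(t, x, k)
            J = model.jac_x_eval(t, x, k)
            return np.concatenate([f, (J @ phi).ravel()])

        try:
            yT, _, _ = integrate_segments(model, fun, grid[l], grid[l + 1], y0,
                                          rtol=rtol, atol=atol,
                                          method=solution.method)
        except SolverError as exc:
            raise SolverError(f"variational solve failed on interval "
                              f"[{grid[l]}, {grid[l + 1]}]: {exc}") from exc
        steps[l] = yT[n:].reshape(n, n)
    mono = None
    if solution.is_periodic:
        mono = eye.copy()
        for l in range(len(grid) - 1):
            mono = steps[l] @ mono
    return VariationalData(grid=grid, step_matrices=steps,
                           solution_kind=solution.kind, monodromy_matrix=mono)


def _grid_index(grid: np.ndarray, t: float) -> int:
    i = int(np.argmin(np.abs(grid - t)))
    if abs(grid[i] - t) > 1e-9 * max(1.0, abs(grid[-1])):
        raise ValueError(f"time {t} is not on the solution grid")
    return i


def fundamental_matrix(data: VariationalData, s: float, t: float) -> np.ndarray:
    """C(s, t): composition of step matrices from time s to time t (s <= t)."""
    i, j = _grid_index(data.grid, s), _grid_index(data.grid, t)
    if i > j:
        raise ValueError("backward maps are not provided: need s <= t")
    out = np.eye(data.n)
    for l in range(i, j):
        out = data.step_matrices[l] @ out
    return out


def monodromy(data: VariationalData) -> np.ndarray:
    """C(0, T) for a periodic solution; eigenvalues are Floquet multipliers."""
    if data.monodromy_matrix is None:
        raise AnalysisError("monodromy is defined for periodic solutions only")
    return data.monodromy_matrix


def liouville_defect(model: CompiledModel, solution: SolutionOfInterest,
                     data: VariationalData) -> float:
    """Max relative mismatch of det(Phi_l) against exp(∫ trace J dt) (oracle)."""
    from scipy.integrate import quad

    k = solution.params
    worst = 0.0
    for l in range(len(data.grid) - 1):
        a, b = data.grid[l], data.grid[l + 1]
        tr, _ = quad(lambda t: np.trace(
            model.jac_x_eval(t, solution(t), k)), a, b, limit=200)
        det = np.linalg.det(data.step_matrices[l])
        worst = max(worst, abs(det - np.exp(tr)) / abs(np.exp(tr)))
    return worst


@dataclass
class SensitivityField:
    """Derivative surfaces ∂g_i/∂k_j(t) over the free parameters."""

    grid: np.ndarray
    param_names: tuple[str, ...]
    raw: np.ndarray  # (N, n, s_free)
    solution: SolutionOfInterest = field(repr=False, default=None)
    rescaled: np.ndarray | None = None
    period_gradient: np.ndarray | None = None  # dtau/dk (autonomous only)
    lambda_convention: str = LAMBDA_CONVENTION

    @property
    def n_params(self) -> int:
        return self.raw.shape[2]

    def column(self, parameter: str) -> np.ndarray:
        """Raw derivative time series (N x n) for one parameter."""
        return self.raw[:, :, self.param_names.index(parameter)]


def _sensitivity_pass(model: CompiledModel, solution: SolutionOfInterest,
                      S0: np.ndarray, with_stm: bool):
    """One forward pass of (x, [Phi], S) over the full span, sampled on the grid."""
    k = solution.params
    n, nf = model.n, len(model.free_indices)
    free = model.free_indices
    eye = np.eye(n)
    pieces = [solution.initial_state]
    if with_stm:
        pieces.append(eye.ravel())
    pieces.append(S0.ravel())
    y0 = np.concatenate(pieces)
    off = n + (n * n if with_stm else 0)

    def fun(t, y):
        x = y[:n]
        f = model.rhs_eval(t, x, k)
        J = model.jac_x_eval(t, x, k)
        B = model.jac_k_eval(t, x, k)[:, free]
        S = y[off:].reshape(n, nf)
        out = [f]
        if with_stm:
            phi = y[n:off].reshape(n, n)
            out.append((J @ phi).ravel())
        out.append((J @ S + B).ravel())
        return np.concatenate(out)

    yT, rows, _ = integrate_segments(model, fun, solution.grid[0],
                                     solution.grid[-1], y0,
                                     t_eval=solution.grid, rtol=solution.rtol,
                                     atol=solution.atol, method=solution.method)
    S_grid = rows[:, off:].reshape(len(solution.grid), n, nf)
    phi_T = yT[n:off].reshape(n, n) if with_stm else None
    return S_grid, phi_T


def solution_derivatives(model: CompiledModel, solution: SolutionOfInterest,
                         data: VariationalData | None = None) -> SensitivityField:
    """Forward sensitivities ∂g/∂k over the free parameters.

    The initial condition is chosen per solution kind (see module docstring);
    for autonomous cycles the bordered solve also returns dτ/dk.
    """
    k = solution.params
    n, free = model.n, model.free_indices
    nf = len(free)
    names = model.free_parameters
    zeros = np.zeros((n, nf))

    if solution.kind == "transient":
        raw, _ = _sensitivity_pass(model, solution, zeros, with_stm=False)
        return SensitivityField(grid=solution.grid, param_names=names, raw=raw,
                                solution=solution)

    # particular response with S(0) = 0 plus the monodromy in one pass
    P_grid, phi_T = _sensitivity_pass(model, solution, zeros, with_stm=True)
    P = P_grid[-1]
    if data is not None and data.monodromy_matrix is not None:
        phi_T = data.monodromy_matrix

    if solution.kind == "forced-periodic":
        A = np.eye(n) - phi_T
        if abs(np.linalg.det(A)) < 1e-12:
            raise SolverError("I - C(0,T) is singular (Floquet multiplier 1); "
                              "the entrained orbit is degenerate")
        S0 = np.linalg.solve(A, P)
        raw, _ = _sensitivity_pass(model, solution, S0, with_stm=False)
        return SensitivityField(grid=solution.grid, param_names=names, raw=raw,
                                solution=solution)

    if solution.kind != "autonomous-periodic":
        raise AnalysisError(f"unknown solution kind {solution.kind!r}")

    x0 = solution.initial_state
    f_end = model.rhs_eval(solution.period, solution.states[-1], k)
    grad_f1 = model.jac_x_eval(0.0, x0, k)[0]
    dk_f1 = model.jac_k_eval(0.0, x0, k)[0, free]
    A = np.zeros((n + 1, n + 1))
    A[:n, :n] = phi_T - np.eye(n)
    A[:n, n] = f_end
    A[n, :n] = grad_f1
    rhs = np.zeros((n + 1, nf))
    rhs[:n] = -P
    rhs[n] = -dk_f1
    sol = np.linalg.solve(A, rhs)
    S0, dtau = sol[:n], sol[n]
    raw, _ = _sensitivity_pass(model, solution, S0, with_stm=False)
    return SensitivityField(grid=solution.grid, param_names=names, raw=raw,
                            solution=solution, period_gradient=dtau)


def rescale_derivatives(field: SensitivityField,
                        solution: SolutionOfInterest | None = None) -> SensitivityField:
    """Fill the period-rescaled (periodic "shape") derivatives in place."""
    solution = solution or field.solution
    if solution.kind == "transient":
        raise AnalysisError("rescaling is undefined for signalling transients: "
                            "their derivatives are inherently non-periodic")
    if solution.kind == "forced-periodic":
        field.rescaled = field.raw.copy()
        return field
    if field.period_gradient is None:
        raise AnalysisError("autonomous rescaling needs the period gradient; "
                            "run solution_derivatives first")
    gdot = solution.state_derivatives()  # (N, n)
    tfrac = solution.grid / solution.period  # (N,)
    # raw + (t/tau) * dtau/dk_j * gdot
    field.rescaled = field.raw + (tfrac[:, None, None]
                                  * gdot[:, :, None]
                                  * field.period_gradient[None, None, :])
    return field


# ---------------------------------------------------------------------------
# Finite-difference oracle (independent of the variational path)
# ---------------------------------------------------------------------------

def finite_difference_derivatives(model: CompiledModel,
                                  solution: SolutionOfInterest,
                                  parameter: str, *, h=None):
    """Central-difference ∂g/∂k_j on the solution grid by re-solving the orbit.

    Used as an independent check of :func:`solution_derivatives`.  Returns
    ``(dg, dtau)`` with ``dtau`` None for non-autonomous kinds.
    """
    from . import trajectory as _traj

    j = model.spec.parameters.index(parameter)
    k = solution.params.copy()
    h = 1e-5 * max(abs(k[j]), 1.0) if h is None else h

    def resolve(kj):
        kp = k.copy()
        kp[j] = kj
        if solution.kind == "autonomous-periodic":
            orb = _traj.find_limit_cycle_autonomous(
                model, kp, solution.initial_state, solution.period,
                pre_periods=0, grid_points=len(solution.grid),
                rtol=solution.rtol, atol=solution.atol, method=solution.method)
            _, states, _ = integrate_segments(
                model, lambda t, y: model.rhs_eval(t, y, kp), 0.0,
                solution.grid[-1], orb.initial_state, t_eval=solution.grid,
                rtol=solution.rtol, atol=solution.atol, method=solution.method)
            return states, orb.period
        if solution.kind == "forced-periodic":
            orb = _traj.find_entrained_orbit(
                model, kp, solution.period, x0_guess=solution.initial_state,
                pre_periods=0, grid_points=len(solution.grid),
                rtol=solution.rtol, atol=solution.atol, method=solution.method)
            return orb.states, orb.period
        _, states, _ = integrate_segments(
            model, lambda t, y: model.rhs_eval(t, y, kp), solution.grid[0],
            solution.grid[-1], solution.initial_state, t_eval=solution.grid,
            rtol=solution.rtol, atol=solution.atol, method=solution.method)
        return states, None

    gp, taup = resolve(k[j] + h)
    gm, taum = resolve(k[j] - h)
    dg = (gp - gm) / (2 * h)
    dtau = None if taup is None else (taup - taum) / (2 * h)
    return dg, dtau
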