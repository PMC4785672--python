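"""System-global sensitivity analysis via SVD of the derivative matrix.

The linearisation of the parameter-to-solution map is flattened onto the
time grid into a matrix ``M = ∂g/∂k`` with one row per (variable-or-
composite, timepoint) and one column per free parameter.  Its singular
value decomposition ``M = U Σ Vᵀ`` yields the principal global
sensitivities ``S_ij = σ_i W_ij`` (``W = Vᵀ``), which express the
first-order solution change ``δg = Σ_ij S_ij δk_j U_i`` and satisfy
``‖δg‖ = ‖S·δk‖``.  The Fisher Information Matrix is ``F = MᵀM = SᵀS``;
concatenating experiments adds their F blocks, which quantifies the
information a new experimental condition contributes.

Rows are weighted by √(Δt) by default so that ‖δg‖² approximates the
continuous L² norm and the spectrum is grid-density invariant; pass
``quadrature_weights=False`` for the unweighted convention.  Weighting is
skipped automatically when an explicit timepoint selection is in force
(discrete observations carry no quadrature measure).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .exceptions import AnalysisError
from .model import CompiledModel
from .trajectory import SolutionOfInterest
from .variational import SensitivityField

__all__ = [
    "Selection",
    "Experiment",
    "DerivativeMatrix",
    "SVDResult",
    "AmplitudePhaseDecomposition",
    "build_experiment",
    "combine_experiments",
    "svd_global",
    "predicted_solution_change",
    "heatmap_fields",
    "variable_removal_analysis",
    "amplitude_phase_decomposition",
    "decompose_period_and_shape",
]


@dataclass(frozen=True)
class Selection:
    """Row/column operations applied when assembling an experiment's block.

    Applied in order: composite variables (linear combinations of variable
    rows at equal times), variable removal, timepoint restriction.
    ``log_params`` rescales column j by k_j (∂g/∂log k_j); ``relative``
    divides each entity's rows by its time-mean level.
    """

    variables: tuple[str, ...] | None = None  # keep-list; None = all
    composites: tuple[tuple[str, tuple[tuple[str, float], ...]], ...] = ()
    timepoints: tuple[float, ...] | None = None
    log_params: bool = False
    relative: bool = False
    use_rescaled: bool = False


@dataclass
class Experiment:
    """A single parameterised model variant with its sensitivity block."""

    name: str
    model: CompiledModel = field(repr=False, default=None)
    solution: SolutionOfInterest = field(repr=False, default=None)
    field_: SensitivityField = field(repr=False, default=None)
    selection: Selection = field(default_factory=Selection)
    values: np.ndarray = None  # (rows, s_free), weights applied
    row_labels: list = None  # (experiment, entity, time)
    col_labels: tuple[str, ...] = ()
    row_weights: np.ndarray = None


def _trapezoid_weights(grid: np.ndarray) -> np.ndarray:
    w = np.empty_like(grid)
    w[0] = (grid[1] - grid[0]) / 2
    w[-1] = (grid[-1] - grid[-2]) / 2
    w[1:-1] = (grid[2:] - grid[:-2]) / 2
    return w


def build_experiment(name, model: CompiledModel, solution: SolutionOfInterest,
                     sens: SensitivityField, selection: Selection | None = None,
                     *, quadrature_weights=True) -> Experiment:
    """Assemble the derivative-matrix block of one experiment."""
    selection = selection or Selection()
    spec = model.spec
    deriv = sens.rescaled if selection.use_rescaled else sens.raw
    if deriv is None:
        raise AnalysisError("rescaled derivatives requested but not computed")
    grid = sens.grid
    states = solution.states

    entities: list[tuple[str, np.ndarray, np.ndarray]] = []  # (name, series, rows NxS)
    kept = spec.variables if selection.variables is None else selection.variables
    unknown = set(kept) - set(spec.variables)
    if unknown:
        raise AnalysisError(f"selection keeps unknown variable(s) {sorted(unknown)}")
    for v in kept:
        m = spec.variables.index(v)
        entities.append((v, states[:, m], deriv[:, m, :]))
    for comp_name, terms in selection.composites:
        series = np.zeros(len(grid))
        rows = np.zeros((len(grid), deriv.shape[2]))
        for var, coef in terms:
            if var not in spec.variables:
                raise AnalysisError(f"composite {comp_name!r} references unknown "
                                    f"or removed variable {var!r}")
            m = spec.variables.index(var)
            series = series + coef * states[:, m]
            rows = rows + coef * deriv[:, m, :]
        entities.append((comp_name, series, rows))

    if selection.timepoints is not None:
        idx = []
        for tp in selection.timepoints:
            i = int(np.argmin(np.abs(grid - tp)))
            if abs(grid[i] - tp) > 1e-6 * max(1.0, grid[-1]):
                raise AnalysisError(f"timepoint {tp} is not on the solution grid")
            idx.append(i)
        idx = np.array(idx)
        weights = np.ones(len(idx))
    else:
        idx = np.arange(len(grid))
        weights = (np.sqrt(_trapezoid_weights(grid)) if quadrature_weights
                   else np.ones(len(grid)))

    blocks, labels, wlist = [], [], []
    for ent_name, series, rows in entities:
        block = rows[idx].copy()
        if selection.relative:
            level = float(np.mean(series))
            if abs(level) < 1e-12:
                raise AnalysisError(f"entity {ent_name!r} has zero mean level; "
                                    "relative scaling is undefined")
            block = block / level
        block = block * weights[:, None]
        blocks.append(block)
        labels.extend((name, ent_name, float(grid[i])) for i in idx)
        wlist.append(weights)
    values = np.vstack(blocks)
    if selection.log_params:
        kfree = solution.params[model.free_indices]
        values = values * kfree[None, :]
    return Experiment(name=name, model=model, solution=solution, field_=sens,
                      selection=selection, values=values, row_labels=labels,
                      col_labels=tuple(sens.param_names),
                      row_weights=np.concatenate(wlist))


@dataclass
class DerivativeMatrix:
    """The flattened (rows x parameters) derivative matrix with labels."""

    values: np.ndarray
    row_labels: list
    col_labels: tuple[str, ...]
    row_weights: np.ndarray | None = None

    @property
    def matrix(self) -> np.ndarray:
        return self.values

    def drop_entity(self, entity: str) -> "DerivativeMatrix":
        keep = [i for i, lbl in enumerate(self.row_labels) if lbl[1] != entity]
        if len(keep) == len(self.row_labels):
            raise KeyError(f"no rows belong to entity {entity!r}")
        w = None if self.row_weights is None else self.row_weights[keep]
        return DerivativeMatrix(values=self.values[keep],
                                row_labels=[self.row_labels[i] for i in keep],
                                col_labels=self.col_labels, row_weights=w)

    @property
    def entities(self) -> list[str]:
        seen = []
        for lbl in self.row_labels:
            if lbl[1] not in seen:
                seen.append(lbl[1])
        return seen


def combine_experiments(experiments) -> DerivativeMatrix:
    """Vertically concatenate experiment blocks (identical parameter columns)."""
    exps = list(experiments)
    if not exps:
        raise ValueError("need at least one experiment")
    cols = exps[0].col_labels
    for e in exps[1:]:
        if e.col_labels != cols:
            raise AnalysisError(f"experiments have mismatched parameter columns: "
                                f"{cols} vs {e.col_labels}")
    values = np.vstack([e.values for e in exps])
    labels = [lbl for e in exps for lbl in e.row_labels]
    weights = np.concatenate([e.row_weights for e in exps])
    return DerivativeMatrix(values=values, row_labels=labels, col_labels=cols,
                            row_weights=weights)


@dataclass
class SVDResult:
    """Thin SVD of M with the principal global sensitivities and the FIM."""

    U: np.ndarray
    singular_values: np.ndarray
    V: np.ndarray
    W: np.ndarray  # V^T
    S: np.ndarray  # diag(sigma) @ W
    F: np.ndarray  # M^T M = S^T S
    row_labels: list = None
    col_labels: tuple[str, ...] = ()

    def pss(self) -> pd.DataFrame:
        """Parameter sensitivity spectrum: S_ij with labelled axes."""
        return pd.DataFrame(self.S, columns=list(self.col_labels),
                            index=[f"PC{i + 1}" for i in range(self.S.shape[0])])

    def pc_time_series(self, i: int) -> dict[str, pd.Series]:
        """Principal component U_i reshaped to one time series per entity."""
        if self.row_labels is None:
            raise AnalysisError("row labels unavailable for this SVD")
        out: dict[str, pd.Series] = {}
        col = self.U[:, i]
        for (exp, ent, tt), val in zip(self.row_labels, col):
            out.setdefault(f"{exp}:{ent}", []).append((tt, val))
        return {key: pd.Series(dict(vals)).sort_index()
                for key, vals in out.items()}


def _as_matrix(M) -> tuple[np.ndarray, list | None, tuple[str, ...]]:
    if isinstance(M, DerivativeMatrix):
        return M.values, M.row_labels, M.col_labels
    arr = np.asarray(M, dtype=float)
    return arr, None, tuple(f"k{j + 1}" for j in range(arr.shape[1]))


def svd_global(M) -> SVDResult:
    """Thin SVD with a deterministic sign convention.

    Each V column's largest-magnitude entry is made positive (ties broken by
    the first index), flipping the paired U column.
    """
    A, row_labels, col_labels = _as_matrix(M)
    if A.size == 0:
        raise ValueError("empty derivative matrix")
    U, sig, Vt = np.linalg.svd(A, full_matrices=False)
    for i in range(Vt.shape[0]):
        j = int(np.argmax(np.abs(Vt[i])))
        if Vt[i, j] < 0:
            Vt[i] = -Vt[i]
            U[:, i] = -U[:, i]
    S = sig[:, None] * Vt
    F = A.T @ A
    return SVDResult(U=U, singular_values=sig, V=Vt.T, W=Vt, S=S, F=F,
                     row_labels=row_labels, col_labels=col_labels)


def predicted_solution_change(result: SVDResult, delta_k) -> np.ndarray:
    """First-order δg = Σ_ij S_ij δk_j U_i (‖δg‖ = ‖S·δk‖ by construction)."""
    delta_k = np.asarray(delta_k, dtype=float)
    if delta_k.shape != (result.S.shape[1],):
        raise ValueError(f"delta_k must have length {result.S.shape[1]}")
    return result.U @ (result.S @ delta_k)


def heatmap_fields(result: SVDResult, m=None, *, kind="value",
                   threshold=None) -> pd.DataFrame:
    """Sensitivity heat-map fields per principal component and entity.

    ``kind="value"`` gives f_{i,m}(t) = (max_j |S_ij|)·|U_{i,m}(t)|,
    ``kind="derivative"`` the time-derivative analogue (centered differences
    of U on the grid), ``kind="scaled_pc"`` gives σ_i·|U_{i,m}(t)|.
    ``threshold`` keeps only (PC, entity) pairs whose maximum exceeds
    threshold × the global maximum.  ``m`` restricts to one entity (name or
    variable index), validated against the row labels.
    """
    if result.row_labels is None:
        raise AnalysisError("heat maps need a labelled derivative matrix")
    entities = []
    for lbl in result.row_labels:
        if lbl[1] not in entities:
            entities.append(lbl[1])
    if m is not None:
        if isinstance(m, (int, np.integer)):
            if not 0 <= m < len(entities):
                raise IndexError(f"entity index {m} out of range "
                                 f"(have {len(entities)})")
            m = entities[m]
        elif m not in entities:
            raise KeyError(f"unknown entity {m!r}; have {entities}")
    n_pc = result.U.shape[1]
    fields: dict[tuple[int, str], pd.Series] = {}
    for i in range(n_pc):
        series = result.pc_time_series(i)
        for key, ts in series.items():
            ent = key.split(":", 1)[1]
            times = ts.index.to_numpy()
            vals = ts.to_numpy()
            if kind == "value":
                mag = np.abs(vals)
                coef = np.abs(result.S[i]).max()
            elif kind == "derivative":
                mag = np.abs(np.gradient(vals, times))
                coef = np.abs(result.S[i]).max()
            elif kind == "scaled_pc":
                mag = np.abs(vals)
                coef = result.singular_values[i]
            else:
                raise ValueError(f"unknown kind {kind!r}")
            fields[(i, key)] = pd.Series(coef * mag, index=times)
    if threshold is not None:
        global_max = max((s.max() for s in fields.values()), default=0.0)
        fields = {key: s for key, s in fields.items()
                  if s.max() >= threshold * global_max - 1e-15}
    if m is not None:
        fields = {key: s for key, s in fields.items()
                  if key[1].split(":", 1)[1] == m}
    return pd.DataFrame({f"PC{i + 1}|{key}": s for (i, key), s in fields.items()})


def variable_removal_analysis(M: DerivativeMatrix) -> pd.Series:
    """Rank variables by the mean |change| in singular values when removed."""
    entities = M.entities
    if len(entities) < 2:
        raise AnalysisError("variable removal analysis needs at least two variables")
    sig_full = np.linalg.svd(M.values, compute_uv=False)
    scores = {}
    for ent in entities:
        reduced = M.drop_entity(ent)
        sig = np.linalg.svd(reduced.values, compute_uv=False)
        padded = np.zeros_like(sig_full)
        padded[:min(len(sig), len(sig_full))] = sig[:len(sig_full)]
        scores[ent] = float(np.mean(np.abs(sig_full - padded)))
    return pd.Series(scores, name="mean |Δσ|").sort_values(ascending=False)


@dataclass
class AmplitudePhaseDecomposition:
    """δg_m split into time-translation, amplitude, and residual parts."""

    variable_index: int
    alpha: float
    beta: float
    residual_norm: float
    basis_translation: np.ndarray  # R_m, unit, ∝ ġ_m on the grid
    basis_amplitude: np.ndarray  # A_m, unit, ⟂ R_m
    residual: np.ndarray


def amplitude_phase_decomposition(delta_g, solution: SolutionOfInterest,
                                  m: int) -> AmplitudePhaseDecomposition:
    """Project a per-variable change onto translation and amplitude modes.

    ``R_m ∝ ġ_m`` represents an infinitesimal time translation, ``A_m`` the
    centred waveform orthogonalised against R_m (an amplitude change);
    (α, β) are the orthogonal projections onto them.
    """
    if not solution.is_periodic:
        raise AnalysisError("the decomposition is defined for periodic solutions")
    delta_g = np.asarray(delta_g, dtype=float)
    gdot = solution.state_derivatives()[:, m]
    norm_dot = np.linalg.norm(gdot)
    if norm_dot < 1e-12:
        raise AnalysisError(f"variable {m} is constant; no translation mode")
    R = gdot / norm_dot
    centered = solution.states[:, m] - solution.states[:, m].mean()
    A0 = centered - (centered @ R) * R
    norm_A = np.linalg.norm(A0)
    if norm_A < 1e-12:
        raise AnalysisError(f"variable {m} has no amplitude mode independent "
                            "of translation")
    A = A0 / norm_A
    alpha = float(delta_g @ R)
    beta = float(delta_g @ A)
    residual = delta_g - alpha * R - beta * A
    return AmplitudePhaseDecomposition(variable_index=int(m), alpha=alpha,
                                       beta=beta,
                                       residual_norm=float(np.linalg.norm(residual)),
                                       basis_translation=R, basis_amplitude=A,
                                       residual=residual)


def decompose_period_and_shape(sens: SensitivityField,
                               solution: SolutionOfInterest | None = None):
    """Split each raw derivative column into period-change and shape-change parts.

    period part = -(t/τ)(dτ/dk_j)·ġ(t); shape part = the period-rescaled
    derivative; the two sum to the raw derivative.
    """
    solution = solution or sens.solution
    if solution.kind != "autonomous-periodic":
        raise AnalysisError("the period/shape split applies to autonomous "
                            "limit cycles only")
    if sens.period_gradient is None:
        raise AnalysisError("run solution_derivatives first (period gradient "
                            "missing)")
    from .variational import rescale_derivatives

    if sens.rescaled is None:
        rescale_derivatives(sens, solution)
    gdot = solution.state_derivatives()
    tfrac = solution.grid / solution.period
    period_part = -(tfrac[:, None, None] * gdot[:, :, None]
                    * sens.period_gradient[None, None, :])
    return period_part, sens.rescaled
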