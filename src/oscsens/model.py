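"""ODE model definition, template parsing, symbolic compilation and export.

A model is a smooth ODE system ``dx/dt = f(t, x, k)`` on variables ``x``
(length n) with parameters ``k`` (length s), optionally driven by piecewise
constant temporal forcing profiles (e.g. a 12:12 light/dark square wave).
Right-hand sides are sympy expressions; compilation produces fast numpy
evaluators for f and its derivative matrices ∂f/∂x, ∂f/∂k and ∂f/∂t, which
everything downstream (variational equation, adjoint, sensitivity fields)
is built on.

Discontinuities enter only through forcing profiles; the compiled model
exposes their switch times so integrators can split time spans there.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import sympy as sp
from sympy.parsing.sympy_parser import (
    convert_xor,
    parse_expr,
    standard_transformations,
)

from .exceptions import ModelCompileError, ModelParseError

__all__ = [
    "ForcingProfile",
    "ModelSpec",
    "CompiledModel",
    "parse_model_template",
    "serialize_model_template",
    "compile_model",
    "evaluate_forcing",
    "export_xpp",
    "export_sbml",
    "read_value_table",
    "write_value_table",
]

_ALLOWED_FUNCTIONS = {
    "exp": sp.exp,
    "log": sp.log,
    "sqrt": sp.sqrt,
    "sin": sp.sin,
    "cos": sp.cos,
    "tan": sp.tan,
    "tanh": sp.tanh,
    "cosh": sp.cosh,
    "sinh": sp.sinh,
    "atan": sp.atan,
}

# Constructs that break the smoothness contract of the variational machinery.
_NON_SMOOTH = (sp.Abs, sp.sign, sp.Max, sp.Min, sp.floor, sp.ceiling,
               sp.Piecewise, sp.Heaviside)

_FORCING_KINDS = ("square-wave", "pulse-train", "constant")


@dataclass(frozen=True)
class ForcingProfile:
    """A deterministic temporal forcing signal.

    ``square-wave`` and ``pulse-train`` are periodic: the value is
    ``high_level`` while ``t mod period`` lies in one of the half-open
    ``on_windows`` ``[start, end)`` and ``low_level`` otherwise.  A
    ``constant`` profile always evaluates to ``high_level``.
    """

    name: str
    kind: str = "square-wave"
    period: float | None = None
    on_windows: tuple[tuple[float, float], ...] = ()
    high_level: float = 1.0
    low_level: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in _FORCING_KINDS:
            raise ModelParseError(
                f"unknown forcing kind {self.kind!r}; expected one of {_FORCING_KINDS}")
        if self.kind == "constant":
            return
        if self.period is None or self.period <= 0:
            raise ModelParseError(f"forcing {self.name!r}: periodic kinds need period > 0")
        windows = sorted(self.on_windows)
        prev_end = 0.0
        for start, end in windows:
            if not (0.0 <= start < end <= self.period):
                raise ModelParseError(
                    f"forcing {self.name!r}: window [{start}, {end}) not inside "
                    f"[0, {self.period})")
            if start < prev_end:
                raise ModelParseError(f"forcing {self.name!r}: overlapping on-windows")
            prev_end = end

    def __call__(self, t: float) -> float:
        if self.kind == "constant":
            return self.high_level
        tau = math.fmod(t, self.period)
        if tau < 0:
            tau += self.period
        for start, end in self.on_windows:
            if start <= tau < end:
                return self.high_level
        return self.low_level

    def switch_times(self) -> list[float]:
        """Discontinuity offsets within one forcing period, sorted."""
        if self.kind == "constant":
            return []
        times = set()
        for start, end in self.on_windows:
            times.add(start % self.period)
            times.add(end % self.period)
        return sorted(times)


def evaluate_forcing(profile: ForcingProfile, t: float) -> float:
    """Evaluate a forcing profile at time ``t`` (t >= 0, half-open windows)."""
    return profile(t)


@dataclass(frozen=True)
class ModelSpec:
    """Symbolic specification of an ODE model.

    ``rhs`` holds one canonical sympy-printable expression string per
    variable; expressions may reference ``t``, variables, parameters, and
    forcing names.  ``fixed_parameters`` are excluded from every sensitivity
    output (typical use: Hill exponents held at their literature values).
    """

    name: str
    variables: tuple[str, ...]
    parameters: tuple[str, ...]
    rhs: tuple[str, ...]
    forcings: tuple[ForcingProfile, ...] = ()
    fixed_parameters: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if len(self.variables) < 1 or len(self.parameters) < 1:
            raise ModelParseError("need at least one variable and one parameter")
        names = (list(self.variables) + list(self.parameters)
                 + [f.name for f in self.forcings])
        dupes = {x for x in names if names.count(x) > 1}
        if dupes:
            raise ModelParseError(f"duplicate names: {sorted(dupes)}")
        if "t" in names:
            raise ModelParseError("'t' is reserved for time")
        if len(self.rhs) != len(self.variables):
            raise ModelParseError("need exactly one equation per variable")
        unknown_fixed = set(self.fixed_parameters) - set(self.parameters)
        if unknown_fixed:
            raise ModelParseError(f"fixed_parameters not declared: {sorted(unknown_fixed)}")

    @property
    def n(self) -> int:
        return len(self.variables)

    @property
    def s(self) -> int:
        return len(self.parameters)

    @property
    def free_parameters(self) -> tuple[str, ...]:
        return tuple(p for p in self.parameters if p not in self.fixed_parameters)

    def sympy_rhs(self) -> list[sp.Expr]:
        syms = self._symbol_table()
        return [_parse_expression(e, syms, context=f"equation for {v}")
                for v, e in zip(self.variables, self.rhs)]

    def _symbol_table(self) -> dict[str, sp.Symbol]:
        table = {"t": sp.Symbol("t")}
        for nm in (*self.variables, *self.parameters, *(f.name for f in self.forcings)):
            table[nm] = sp.Symbol(nm)
        return table


def _parse_expression(text: str, symbols: dict[str, sp.Symbol],
                      context: str = "expression", line: int | None = None) -> sp.Expr:
    local = dict(_ALLOWED_FUNCTIONS)
    local.update(symbols)
    where = f"{context}" + (f" (line {line})" if line is not None else "")
    try:
        expr = parse_expr(text, local_dict=local, evaluate=True,
                          transformations=standard_transformations + (convert_xor,))
    except Exception as exc:  # sympy raises a zoo of error types
        raise ModelParseError(f"cannot parse {where}: {text!r} ({exc})") from exc
    stray = [str(s) for s in expr.free_symbols if str(s) not in symbols]
    if stray:
        raise ModelParseError(
            f"undeclared symbol(s) {sorted(stray)} in {where}: {text!r}")
    return expr


# ---------------------------------------------------------------------------
# Template format
# ---------------------------------------------------------------------------

def parse_model_template(text: str) -> ModelSpec:
    """Parse the sectioned plain-text model template format.

    Grammar (see docs/model_format.md): a ``model NAME`` line, then sections
    ``variables:``, ``parameters:``, optional ``fixed:``, ``equations:``
    (one ``d<var>/dt = expr`` line each) and optional ``forcings:``.
    """
    name = "model"
    variables: list[str] = []
    parameters: list[str] = []
    fixed: list[str] = []
    equations: dict[str, tuple[str, int]] = {}
    forcings: list[ForcingProfile] = []
    section = None
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        low = line.lower()
        if low.startswith("model "):
            name = line.split(None, 1)[1].strip()
            continue
        matched = False
        for sec in ("variables", "parameters", "fixed", "equations", "forcings"):
            if low == sec + ":" or low.startswith(sec + ":"):
                section = sec
                line = line[len(sec) + 1:].strip()
                matched = True
                break
        if matched and not line:
            continue
        if section is None:
            raise ModelParseError(f"line {lineno}: content before any section: {raw!r}")
        if section in ("variables", "parameters", "fixed"):
            items = [w for w in line.replace(",", " ").split() if w]
            target = {"variables": variables, "parameters": parameters,
                      "fixed": fixed}[section]
            target.extend(items)
        elif section == "equations":
            eq = _parse_equation_line(line, lineno)
            equations[eq[0]] = (eq[1], lineno)
        elif section == "forcings":
            forcings.append(_parse_forcing_line(line, lineno))
    missing = [v for v in variables if v not in equations]
    if missing:
        raise ModelParseError(f"no equation given for variable(s) {missing}")
    extra = [v for v in equations if v not in variables]
    if extra:
        raise ModelParseError(f"equation(s) for undeclared variable(s) {extra}")
    spec = ModelSpec(name=name, variables=tuple(variables),
                     parameters=tuple(parameters),
                     rhs=tuple(equations[v][0] for v in variables),
                     forcings=tuple(forcings), fixed_parameters=tuple(fixed))
    # Canonicalise rhs strings through sympy so round-tripping is exact, and
    # surface undeclared-symbol errors with their line numbers.
    syms = spec._symbol_table()
    canon = []
    for v in variables:
        raw_expr, lineno = equations[v]
        expr = _parse_expression(raw_expr, syms, context=f"equation for {v}", line=lineno)
        canon.append(sp.sstr(expr))
    return replace(spec, rhs=tuple(canon))


def _parse_equation_line(line: str, lineno: int) -> tuple[str, str]:
    if "=" not in line:
        raise ModelParseError(f"line {lineno}: equation needs '=': {line!r}")
    lhs, rhs = (part.strip() for part in line.split("=", 1))
    var = None
    if lhs.startswith("d") and lhs.endswith("/dt"):
        var = lhs[1:-3]
    elif lhs.endswith("'"):
        var = lhs[:-1]
    if not var:
        raise ModelParseError(
            f"line {lineno}: equation left side must be 'd<var>/dt' or \"<var>'\": {lhs!r}")
    return var, rhs


def _parse_forcing_line(line: str, lineno: int) -> ForcingProfile:
    parts = line.split()
    if len(parts) < 2:
        raise ModelParseError(f"line {lineno}: forcing needs 'NAME KIND key=value...'")
    name, kind = parts[0], parts[1]
    kw: dict[str, str] = {}
    for tok in parts[2:]:
        if "=" not in tok:
            raise ModelParseError(f"line {lineno}: bad forcing option {tok!r}")
        key, val = tok.split("=", 1)
        kw[key] = val
    try:
        if kind == "constant":
            level = float(kw.get("level", kw.get("high", "1.0")))
            return ForcingProfile(name=name, kind="constant",
                                  high_level=level, low_level=level)
        windows = []
        for win in kw.get("on", "").split(","):
            if not win:
                continue
            start, end = win.split(":")
            windows.append((float(start), float(end)))
        return ForcingProfile(name=name, kind=kind, period=float(kw["period"]),
                              on_windows=tuple(windows),
                              high_level=float(kw.get("high", "1.0")),
                              low_level=float(kw.get("low", "0.0")))
    except (KeyError, ValueError) as exc:
        raise ModelParseError(f"line {lineno}: bad forcing line {line!r} ({exc})") from exc


def serialize_model_template(spec: ModelSpec) -> str:
    """Render a ModelSpec back to template text; inverse of parse."""
    lines = [f"model {spec.name}", f"variables: {' '.join(spec.variables)}",
             f"parameters: {' '.join(spec.parameters)}"]
    if spec.fixed_parameters:
        lines.append(f"fixed: {' '.join(spec.fixed_parameters)}")
    lines.append("equations:")
    for v, e in zip(spec.variables, spec.rhs):
        lines.append(f"    d{v}/dt = {e}")
    if spec.forcings:
        lines.append("forcings:")
        for f in spec.forcings:
            if f.kind == "constant":
                lines.append(f"    {f.name} constant level={f.high_level!r}")
            else:
                on = ",".join(f"{a!r}:{b!r}" for a, b in f.on_windows)
                lines.append(f"    {f.name} {f.kind} period={f.period!r} "
                             f"high={f.high_level!r} low={f.low_level!r} on={on}")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Compilation
# ---------------------------------------------------------------------------

@dataclass
class CompiledModel:
    """Machine-evaluable form of a ModelSpec.

    All evaluators take ``(t, x, k)`` with ``x`` of length n and ``k`` the
    full parameter vector of length s ordered as ``spec.parameters``.
    """

    spec: ModelSpec
    rhs_sym: list[sp.Expr] = field(repr=False, default_factory=list)
    _fn_rhs: object = field(repr=False, default=None)
    _fn_jac_x: object = field(repr=False, default=None)
    _fn_jac_k: object = field(repr=False, default=None)
    _fn_dfdt: object = field(repr=False, default=None)

    @property
    def n(self) -> int:
        return self.spec.n

    @property
    def s(self) -> int:
        return self.spec.s

    @property
    def free_parameters(self) -> tuple[str, ...]:
        return self.spec.free_parameters

    @property
    def free_indices(self) -> np.ndarray:
        fixed = set(self.spec.fixed_parameters)
        return np.array([i for i, p in enumerate(self.spec.parameters)
                         if p not in fixed], dtype=int)

    def param_vector(self, params) -> np.ndarray:
        """Normalise a {name: value} mapping or sequence to an ordered array."""
        if isinstance(params, dict):
            missing = [p for p in self.spec.parameters if p not in params]
            if missing:
                raise KeyError(f"missing parameter value(s): {missing}")
            return np.array([float(params[p]) for p in self.spec.parameters])
        k = np.asarray(params, dtype=float)
        if k.shape != (self.s,):
            raise ValueError(f"expected {self.s} parameter values, got shape {k.shape}")
        return k

    def _forcing_values(self, t: float) -> list[float]:
        return [f(t) for f in self.spec.forcings]

    def rhs_eval(self, t: float, x, k) -> np.ndarray:
        u = self._forcing_values(t)
        return np.asarray(self._fn_rhs(t, *x, *k, *u), dtype=float).ravel()

    def jac_x_eval(self, t: float, x, k) -> np.ndarray:
        u = self._forcing_values(t)
        return np.asarray(self._fn_jac_x(t, *x, *k, *u), dtype=float).reshape(self.n, self.n)

    def jac_k_eval(self, t: float, x, k) -> np.ndarray:
        u = self._forcing_values(t)
        return np.asarray(self._fn_jac_k(t, *x, *k, *u), dtype=float).reshape(self.n, self.s)

    def dfdt_eval(self, t: float, x, k) -> np.ndarray:
        """Explicit partial ∂f/∂t (forcings held constant)."""
        u = self._forcing_values(t)
        return np.asarray(self._fn_dfdt(t, *x, *k, *u), dtype=float).ravel()

    def second_derivative(self, t: float, x, k) -> np.ndarray:
        """d²x/dt² = J·f + ∂f/∂t along a trajectory (away from switch times)."""
        f = self.rhs_eval(t, x, k)
        return self.jac_x_eval(t, x, k) @ f + self.dfdt_eval(t, x, k)

    @property
    def switch_times(self) -> tuple[float, ...]:
        times = set()
        for f in self.spec.forcings:
            times.update(f.switch_times())
        return tuple(sorted(times))

    @property
    def forcing_period(self) -> float | None:
        """Common period of the periodic forcings (None if unforced)."""
        periods = {f.period for f in self.spec.forcings if f.kind != "constant"}
        if not periods:
            return None
        if len(periods) > 1:
            raise ModelCompileError(f"multiple forcing periods {sorted(periods)}; "
                                    "entrainment analysis needs a single one")
        return periods.pop()

    def breakpoints(self, t0: float, t1: float) -> np.ndarray:
        """Forcing discontinuity times strictly inside (t0, t1)."""
        period = None
        offsets: set[float] = set()
        for f in self.spec.forcings:
            if f.kind == "constant":
                continue
            period = f.period
            offsets.update(f.switch_times())
        if period is None or not offsets:
            return np.empty(0)
        j0 = math.floor(t0 / period) - 1
        j1 = math.ceil(t1 / period) + 1
        pts = [j * period + off for j in range(j0, j1 + 1) for off in offsets]
        eps = 1e-12 * max(1.0, abs(t0), abs(t1))
        return np.array(sorted(p for p in pts if t0 + eps < p < t1 - eps))


def compile_model(spec: ModelSpec) -> CompiledModel:
    """Symbolically differentiate the right-hand side and lambdify everything."""
    syms = spec._symbol_table()
    t = syms["t"]
    xs = [syms[v] for v in spec.variables]
    ks = [syms[p] for p in spec.parameters]
    us = [syms[f.name] for f in spec.forcings]
    exprs = spec.sympy_rhs()
    for v, e in zip(spec.variables, exprs):
        bad = [type(a).__name__ for a in e.atoms(sp.Function, sp.Abs)
               if isinstance(a, _NON_SMOOTH)]
        bad += [type(a).__name__ for a in e.atoms(*_NON_SMOOTH)]
        if bad:
            raise ModelCompileError(
                f"equation for {v} uses non-differentiable construct(s) "
                f"{sorted(set(bad))}; reformulate smoothly (discontinuities are "
                "supported only through forcing profiles)")
    f = sp.Matrix(exprs)
    args = [t, *xs, *ks, *us]
    jac_x = f.jacobian(xs)
    jac_k = f.jacobian(ks)
    dfdt = f.diff(t)
    lam = lambda m: sp.lambdify(args, m, modules="numpy")
    return CompiledModel(spec=spec, rhs_sym=exprs, _fn_rhs=lam(f),
                         _fn_jac_x=lam(jac_x), _fn_jac_k=lam(jac_k),
                         _fn_dfdt=lam(dfdt))


# ---------------------------------------------------------------------------
# Parameter / initial-condition tables
# ---------------------------------------------------------------------------

def read_value_table(path) -> dict[str, float]:
    """Read a two-column name,value CSV (header optional)."""
    import pandas as pd

    df = pd.read_csv(path, header=None, comment="#")
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns (name,value)")
    first = str(df.iloc[0, 0]).strip().lower()
    if first in ("name", "parameter", "variable"):
        df = df.iloc[1:]
    return {str(k).strip(): float(v) for k, v in zip(df.iloc[:, 0], df.iloc[:, 1])}


def write_value_table(path, values: dict[str, float]) -> None:
    with open(path, "w") as fh:
        fh.write("name,value\n")
        for k, v in values.items():
            fh.write(f"{k},{v!r}\n")


# ---------------------------------------------------------------------------
# Exports
# ---------------------------------------------------------------------------

def _require_all(names, table, what: str) -> None:
    missing = [n for n in names if n not in table]
    if missing:
        raise ValueError(f"missing {what} value(s): {missing}")


def export_xpp(spec: ModelSpec, params: dict[str, float],
               ics: dict[str, float]) -> str:
    """Render an XPPAUT .ode file (full 17-significant-digit numerics).

    Periodic forcings are inlined with XPP's ``heav``/``mod`` built-ins.
    """
    _require_all(spec.parameters, params, "parameter")
    _require_all(spec.variables, ics, "initial condition")
    lines = [f"# {spec.name} (exported by oscsens)"]
    for f in spec.forcings:
        if f.kind == "constant":
            lines.append(f"{f.name}={f.high_level!r}")
        else:
            terms = [f"heav(mod(t,{f.period!r})-({a!r}))*heav(({b!r})-mod(t,{f.period!r}))"
                     for a, b in f.on_windows]
            amp = f.high_level - f.low_level
            lines.append(f"{f.name}={f.low_level!r}+({amp!r})*({'+'.join(terms) or '0'})")
    for v, e in zip(spec.variables, spec.rhs):
        lines.append(f"d{v}/dt={e.replace('**', '^')}")
    for p in spec.parameters:
        lines.append(f"par {p}={float(params[p]):.17g}")
    for v in spec.variables:
        lines.append(f"init {v}={float(ics[v]):.17g}")
    lines.append("done")
    return "\n".join(lines) + "\n"


def export_sbml(spec: ModelSpec, params: dict[str, float],
                ics: dict[str, float]) -> str:
    """Export the ODEs as an SBML Level 2 document with one rate rule per variable."""
    import libsbml

    if spec.forcings:
        raise ValueError("SBML export supports unforced models only; inline the "
                         "forcing as a smooth expression first")
    if not ics:
        raise ValueError("initial conditions are required for SBML export")
    _require_all(spec.parameters, params, "parameter")
    _require_all(spec.variables, ics, "initial condition")

    doc = libsbml.SBMLDocument(2, 4)
    model = doc.createModel()
    model.setId(_sbml_id(spec.name))
    comp = model.createCompartment()
    comp.setId("cell")
    comp.setSize(1.0)
    comp.setConstant(True)
    for v in spec.variables:
        sps = model.createSpecies()
        sps.setId(v)
        sps.setCompartment("cell")
        sps.setInitialAmount(float(ics[v]))
        sps.setBoundaryCondition(True)
    for p in spec.parameters:
        par = model.createParameter()
        par.setId(p)
        par.setValue(float(params[p]))
        par.setConstant(True)
    for v, e in zip(spec.variables, spec.rhs):
        rule = model.createRateRule()
        rule.setVariable(v)
        math_ast = libsbml.parseL3Formula(e.replace("**", "^"))
        if math_ast is None:
            raise ValueError(f"unsupported construct in equation for {v}: {e!r}")
        rule.setMath(math_ast)
    doc.checkInternalConsistency()
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR):
        msgs = [doc.getError(i).getMessage()
                for i in range(doc.getNumErrors())]
        raise ValueError("SBML export failed consistency check: " + "; ".join(msgs))
    return libsbml.writeSBMLToString(doc)


def _sbml_id(name: str) -> str:
    out = "".join(c if c.isalnum() or c == "_" else "_" for c in name)
    return out if out and not out[0].isdigit() else "m_" + out
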