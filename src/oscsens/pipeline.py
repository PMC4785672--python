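"""End-to-end analysis pipeline driven by a YAML configuration.

A config names the model (built-in fixture or template path), its
parameters, the solution kind, and the analyses to run; the pipeline writes
one CSV per analysis plus a metadata sidecar recording the configuration,
tolerances and package version.  Everything is deterministic: re-running a
config reproduces the tables bit for bit.
"""

from __future__ import annotations

import json
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .exceptions import AnalysisError, OscsensError
from .fixtures import FIXTURES, fixture, fixture_info
from .model import compile_model, parse_model_template, read_value_table
from .response import adjoint_solution, irc, period_derivatives, phase_derivatives, phase_irc
from .svd import Selection, build_experiment, combine_experiments, svd_global
from .trajectory import (detect_phase_events, find_entrained_orbit,
                         find_limit_cycle_autonomous, find_signalling_solution,
                         simulate)
from .variational import compute_step_matrices, rescale_derivatives, solution_derivatives

__all__ = ["run_pipeline", "load_model_from_config"]


class StageError(OscsensError):
    def __init__(self, stage, exc):
        super().__init__(f"stage {stage!r} failed: {exc}")
        self.stage = stage


def load_model_from_config(cfg: dict):
    """Resolve (CompiledModel, params dict, ics dict) from a config mapping."""
    name = cfg.get("model")
    if name in FIXTURES:
        spec, params, ics = fixture(name)
        info = fixture_info(name)
    else:
        spec = parse_model_template(Path(name).read_text())
        params, ics, info = {}, {}, {}
    if isinstance(cfg.get("params"), str):
        params.update(read_value_table(cfg["params"]))
    elif isinstance(cfg.get("params"), dict):
        params.update(cfg["params"])
    if isinstance(cfg.get("ics"), str):
        ics.update(read_value_table(cfg["ics"]))
    elif isinstance(cfg.get("ics"), dict):
        ics.update(cfg["ics"])
    return compile_model(spec), params, ics, info


def _solve(cfg, model, params, ics, info):
    kind = cfg.get("kind", info.get("kind", "transient"))
    x0 = np.array([ics[v] for v in model.spec.variables])
    rtol = float(cfg.get("rtol", 1e-9))
    atol = float(cfg.get("atol", 1e-12))
    grid_points = int(cfg.get("grid_points", 241))
    if kind == "autonomous-periodic":
        return find_limit_cycle_autonomous(
            model, params, x0, cfg.get("guess_period", info.get("guess_period")),
            grid_points=grid_points, rtol=rtol, atol=atol)
    if kind == "forced-periodic":
        return find_entrained_orbit(model, params, x0_guess=x0,
                                    grid_points=grid_points, rtol=rtol, atol=atol)
    if kind == "transient":
        stim = dict(params)
        stim.update(cfg.get("stimulated_params", info.get("stimulated", {})))
        horizon = float(cfg.get("horizon", 20.0))
        if cfg.get("stimulated_params") or info.get("stimulated"):
            return find_signalling_solution(model, params, stim, horizon,
                                            x0_guess=x0, rtol=rtol, atol=atol)
        return simulate(model, params, x0, (0.0, horizon), rtol=rtol, atol=atol)
    raise AnalysisError(f"unknown solution kind {kind!r}")


def run_pipeline(config, outdir) -> Path:
    """Run compile → solve → variational → requested analyses; write CSVs.

    ``config`` is a mapping or a path to a YAML file.  Returns the output
    directory.  Any stage failure is re-raised annotated with the stage name.
    """
    if not isinstance(config, dict):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log: list[str] = []
    written: list[str] = []

    def emit(name, df):
        path = outdir / name
        df.to_csv(path, index=False, float_format="%.12g")
        written.append(name)
        log.append(f"wrote {name} ({df.shape[0]} rows)")

    def stage(name, fn):
        try:
            out = fn()
            log.append(f"stage {name}: ok")
            return out
        except Exception as exc:
            log.append(f"stage {name}: FAILED ({exc}); partial outputs: {written}")
            (outdir / "pipeline.log").write_text("\n".join(log) + "\n")
            raise StageError(name, exc) from exc

    model, params, ics, info = stage("compile",
                                     lambda: load_model_from_config(config))
    solution = stage("solve", lambda: _solve(config, model, params, ics, info))

    orbit = pd.DataFrame(solution.states, columns=list(model.spec.variables))
    orbit.insert(0, "time", solution.grid)
    emit("orbit.csv", orbit)

    analyses = list(config.get("analyses", ["derivs"]))
    need_var = bool({"derivs", "irc", "phase", "svd", "design"} & set(analyses))
    data = stage("variational", lambda: compute_step_matrices(model, solution)) \
        if need_var else None
    field = None
    if need_var:
        field = stage("derivatives",
                      lambda: solution_derivatives(model, solution, data))

    if "derivs" in analyses:
        def table():
            if solution.is_periodic:
                rescale_derivatives(field, solution)
            rows = []
            for li, t in enumerate(field.grid):
                for mi, v in enumerate(model.spec.variables):
                    for ji, pname in enumerate(field.param_names):
                        rows.append((t, v, pname, field.raw[li, mi, ji],
                                     field.rescaled[li, mi, ji]
                                     if field.rescaled is not None else np.nan))
            return pd.DataFrame(rows, columns=["time", "variable", "parameter",
                                               "raw", "rescaled"])
        emit("derivs.csv", stage("derivs", table))

    if "irc" in analyses:
        def run_irc():
            adj = adjoint_solution(model, solution, data)
            curves = irc(model, solution, adj)
            rows = [(c.parameter, t, v) for c in curves
                    for t, v in zip(c.phi, c.values)]
            emit("irc.csv", pd.DataFrame(rows, columns=["parameter", "phi", "value"]))
            pder = period_derivatives(curves)
            emit("period_derivatives.csv",
                 pder.rename_axis("parameter").reset_index(name="dtau_dk"))
        stage("irc", run_irc)

    if "phase" in analyses:
        def run_phase():
            if solution.kind != "forced-periodic":
                raise AnalysisError("phase analysis applies to entrained forced "
                                    "oscillators only")
            var = config.get("phase_variable", model.spec.variables[0])
            m = model.spec.variables.index(var)
            events = detect_phase_events(solution, m)
            peaks = [e for e in events if e.kind == "peak"]
            event = peaks[int(config.get("phase_peak_index", 0))]
            pder = phase_derivatives(model, solution, field, event)
            emit("phase_derivatives.csv",
                 pder.rename_axis("parameter").reset_index(name="dphi_dk"))
            rows = [(q.parameter, t, v, q.point_term, q.signed_area)
                    for q in phase_irc(model, solution, data, event)
                    for t, v in zip(q.phi, q.curve)]
            emit("phase_irc.csv",
                 pd.DataFrame(rows, columns=["parameter", "phi", "value",
                                             "point_term", "signed_area"]))
        stage("phase", run_phase)

    if "svd" in analyses:
        def run_svd():
            sel = Selection(log_params=bool(config.get("log_params", False)))
            exp = build_experiment(config.get("name", "experiment"), model,
                                   solution, field, sel,
                                   quadrature_weights=config.get(
                                       "quadrature_weights", True))
            res = svd_global(combine_experiments([exp]))
            emit("singular_values.csv",
                 pd.DataFrame({"index": np.arange(1, len(res.singular_values) + 1),
                               "sigma": res.singular_values}))
            pss = res.pss().reset_index(names="pc")
            emit("pss.csv", pss)
        stage("svd", run_svd)

    if "design" in analyses:
        def run_design():
            knockout = config.get("design_knockout")
            if not knockout:
                raise AnalysisError("design analysis needs 'design_knockout': "
                                    "the rate parameter to zero out")
            ko_params = dict(params)
            if knockout not in ko_params:
                raise AnalysisError(f"unknown parameter {knockout!r}")
            ko_params[knockout] = 0.0
            # a knocked-out oscillator may not cycle: use a transient readout
            horizon = float(config.get("design_horizon",
                                       2 * (solution.period or 20.0)))
            ko_sol = simulate(model, ko_params, solution.initial_state,
                              (0.0, horizon), n_points=len(solution.grid))
            ko_field = solution_derivatives(model, ko_sol)
            wt = build_experiment("wild-type", model, solution, field)
            ko = build_experiment(f"{knockout}-knockout", model, ko_sol, ko_field)
            res_wt = svd_global(combine_experiments([wt]))
            res_all = svd_global(combine_experiments([wt, ko]))
            eig_wt = np.sort(np.linalg.eigvalsh(res_wt.F))[::-1]
            eig_all = np.sort(np.linalg.eigvalsh(res_all.F))[::-1]
            emit("design.csv",
                 pd.DataFrame({"index": np.arange(1, len(eig_wt) + 1),
                               "fim_eigenvalue_wildtype": eig_wt,
                               "fim_eigenvalue_combined": eig_all}))
        stage("design", run_design)

    meta = {
        "oscsens_version": __version__,
        "config": {k: v for k, v in config.items()},
        "tolerances": {"rtol": float(config.get("rtol", 1e-9)),
                       "atol": float(config.get("atol", 1e-12))},
        "seed": config.get("seed"),
        "outputs": written,
        "timestamp": None if config.get("deterministic_metadata", True)
        else time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    (outdir / "metadata.json").write_text(json.dumps(meta, indent=2, sort_keys=True,
                                                     default=str) + "\n")
    (outdir / "pipeline.log").write_text("\n".join(log) + "\n")
    return outdir
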