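"""Adjoint solutions, IRCs, period/phase derivatives, phase IRCs."""

import math

import numpy as np
import pytest

from oscsens.exceptions import AnalysisError
from oscsens.fixtures import fixture, fixture_compiled
from oscsens.model import ForcingProfile, ModelSpec, compile_model, parse_model_template, \
    serialize_model_template
from oscsens.response import (adjoint_solution, classical_coefficient, irc,
                              period_derivatives, phase_derivatives, phase_irc,
                              rank_parameters, window_response)
from oscsens.trajectory import (detect_phase_events, find_entrained_orbit,
                                find_limit_cycle_autonomous, simulate)
from oscsens.variational import (compute_step_matrices,
                                 finite_difference_derivatives,
                                 solution_derivatives)

W = 2 * math.pi


@pytest.fixture(scope="module")
def lam_adjoint(lam_model, lam_cycle, lam_var):
    model, _, _ = lam_model
    data, _ = lam_var
    return adjoint_solution(model, lam_cycle, data)


@pytest.fixture(scope="module")
def lam_ircs(lam_model, lam_cycle, lam_adjoint):
    model, _, _ = lam_model
    return irc(model, lam_cycle, lam_adjoint)


@pytest.fixture(scope="module")
def goodwin_ircs(goodwin_model, goodwin_cycle, goodwin_var):
    model, _, _ = goodwin_model
    data, _ = goodwin_var
    adj = adjoint_solution(model, goodwin_cycle, data)
    return irc(model, goodwin_cycle, adj)


class TestAdjoint:
    def test_lambda_omega_tangential_component(self, lam_cycle, lam_adjoint):
        """Isochrons of the lambda-omega system are radial: Z = (-y, x)/omega."""
        tang = np.einsum("ln,ln->l", lam_adjoint.Z,
                         np.column_stack([-lam_cycle.states[:, 1],
                                          lam_cycle.states[:, 0]]))
        assert np.abs(tang - 1 / W).max() < 1e-8

    def test_normalization_everywhere(self, goodwin_cycle, goodwin_model,
                                      goodwin_var):
        model, _, _ = goodwin_model
        data, _ = goodwin_var
        adj = adjoint_solution(model, goodwin_cycle, data)
        zf = np.einsum("ln,ln->l", adj.Z, goodwin_cycle.state_derivatives())
        assert np.abs(zf - 1.0).max() <= 1e-6

    def test_periodicity(self, goodwin_model, goodwin_cycle, goodwin_var):
        model, _, _ = goodwin_model
        data, _ = goodwin_var
        adj = adjoint_solution(model, goodwin_cycle, data)
        scale = np.abs(adj.Z).max()
        assert np.abs(adj.Z[0] - adj.Z[-1]).max() <= 1e-6 * scale

    def test_forced_solution_rejected(self, forced_model, forced_orbit,
                                      forced_var):
        model, _, _ = forced_model
        with pytest.raises(AnalysisError, match="autonomous"):
            adjoint_solution(model, forced_orbit, forced_var[0])


class TestIRC:
    def test_lambda_omega_constant_curve(self, lam_ircs):
        c = lam_ircs[0]
        assert np.abs(c.values + 1 / W).max() <= 1e-6
        assert c.signed_area == pytest.approx(-1 / W, abs=1e-9)

    def test_window_response_closed_form(self, lam_ircs):
        c = lam_ircs[0]
        assert window_response(c, 0.0, 0.5, 0.01) == pytest.approx(
            -0.01 / (4 * math.pi), rel=1e-6)
        # full window reproduces dk * dtau/dk
        assert window_response(c, 0.0, 1.0, 0.01) == pytest.approx(
            0.01 * c.signed_area, rel=1e-9)
        assert window_response(c, 0.3, 0.3, 0.01) == 0.0

    def test_window_outside_period_rejected(self, lam_ircs):
        with pytest.raises(ValueError, match="outside"):
            window_response(lam_ircs[0], 0.5, 1.5, 0.01)

    def test_absent_parameter_gives_zero_curve(self):
        spec = ModelSpec(name="lam2", variables=("x", "y"),
                         parameters=("w", "unused"),
                         rhs=("x*(1 - x**2 - y**2) - w*y",
                              "y*(1 - x**2 - y**2) + w*x"))
        model = compile_model(spec)
        sol = find_limit_cycle_autonomous(model, [W, 3.0], [1.0, 0.0], 1.0)
        data = compute_step_matrices(model, sol)
        adj = adjoint_solution(model, sol, data)
        curves = irc(model, sol, adj)
        unused = [c for c in curves if c.parameter == "unused"][0]
        assert np.abs(unused.values).max() == 0.0

    def test_pulse_oracle_goodwin(self, goodwin_model, goodwin_cycle,
                                  goodwin_ircs):
        """A finite pulse's asymptotic peak-time shift equals dk times the
        IRC area over the pulse window (first-order, 5 %)."""
        dk = 1e-3
        phi1, phi2 = 5.0, 8.0
        curve = [c for c in goodwin_ircs if c.parameter == "b"][0]
        predicted = window_response(curve, phi1, phi2, dk)

        spec, params, _ = fixture("goodwin")
        pulsed_spec = ModelSpec(
            name="goodwin_pulsed", variables=spec.variables,
            parameters=spec.parameters + ("db",),
            rhs=tuple(e.replace("b*x", "(b + db*P)*x") for e in spec.rhs),
            forcings=(ForcingProfile(name="P", kind="pulse-train", period=1e5,
                                     on_windows=((phi1, phi2),)),),
            fixed_parameters=spec.fixed_parameters)
        pulsed = compile_model(pulsed_spec)
        x0 = goodwin_cycle.initial_state
        # long horizon: the slow Floquet mode (multiplier ~0.63) must decay
        # before the asymptotic peak shift is measured
        T_end = 25 * goodwin_cycle.period

        def last_peak(db):
            k = dict(params)
            k["db"] = db
            sol = simulate(pulsed, k, x0, (0.0, T_end), n_points=1250)
            from scipy.optimize import minimize_scalar

            lo = T_end - 1.5 * goodwin_cycle.period
            hi = T_end - 0.5 * goodwin_cycle.period
            window = (sol.grid > lo) & (sol.grid < hi)
            i0 = np.argmax(np.where(window, sol.states[:, 0], -np.inf))
            res = minimize_scalar(lambda t: -sol(t)[0],
                                  bounds=(sol.grid[i0 - 2], sol.grid[i0 + 2]),
                                  method="bounded",
                                  options={"xatol": 1e-10})
            return res.x

        shift = last_peak(dk) - last_peak(0.0)
        assert shift == pytest.approx(predicted, rel=0.05)


class TestPeriodDerivatives:
    def test_lambda_omega_closed_form(self, lam_ircs):
        pder = period_derivatives(lam_ircs)
        assert pder["w"] == pytest.approx(-2 * math.pi / W**2, rel=1e-6)

    def test_finite_difference_oracle(self, lam_model, lam_cycle, lam_ircs):
        model, _, _ = lam_model
        _, dtau = finite_difference_derivatives(model, lam_cycle, "w")
        assert period_derivatives(lam_ircs)["w"] == pytest.approx(dtau, rel=1e-6)

    def test_goodwin_matches_bordered_solve(self, goodwin_ircs, goodwin_var):
        _, field = goodwin_var
        pder = period_derivatives(goodwin_ircs)
        assert np.abs(pder.to_numpy() - field.period_gradient).max() <= 1e-6

    def test_relative_scaling_and_sort(self, goodwin_ircs):
        rel = period_derivatives(goodwin_ircs, scale="relative", sort="abs")
        c = goodwin_ircs[0]
        assert rel[c.parameter] == pytest.approx(
            c.signed_area * c.param_value / c.period)
        assert list(rel.abs().values) == sorted(rel.abs().values, reverse=True)

    def test_rank_parameters(self, goodwin_ircs):
        order = rank_parameters(goodwin_ircs, by="area")
        areas = {c.parameter: abs(c.signed_area) for c in goodwin_ircs}
        assert order == sorted(areas, key=areas.get, reverse=True)


class TestGridInvariance:
    def test_response_quantities_stable_under_grid_doubling(self, goodwin_model,
                                                            goodwin_cycle,
                                                            goodwin_ircs):
        """Period derivatives and IRC values barely move when the analysis
        grid density is doubled."""
        model, params, _ = goodwin_model
        fine = find_limit_cycle_autonomous(model, params,
                                           goodwin_cycle.initial_state,
                                           goodwin_cycle.period, pre_periods=0,
                                           grid_points=481)
        data = compute_step_matrices(model, fine)
        adj = adjoint_solution(model, fine, data)
        fine_ircs = irc(model, fine, adj)
        coarse = period_derivatives(goodwin_ircs).to_numpy()
        refined = period_derivatives(fine_ircs).to_numpy()
        scale = np.abs(refined).max()
        assert np.abs(coarse - refined).max() <= 1e-6 * scale
        for c_co, c_fi in zip(goodwin_ircs, fine_ircs):
            vscale = np.abs(c_fi.values).max()
            assert np.abs(c_co.values - c_fi.values[::2]).max() <= 1e-6 * vscale


class TestPhaseDerivatives:
    def test_finite_difference_oracle(self, forced_model, forced_orbit,
                                      forced_var):
        """Re-entrain at k_j +/- h and re-detect the peak: implicit
        differentiation must match within 1e-3 relative."""
        model, params, _ = forced_model
        _, field = forced_var
        event = [e for e in detect_phase_events(forced_orbit, 0)
                 if e.kind == "peak"][0]
        pder = phase_derivatives(model, forced_orbit, field, event)
        k0 = forced_orbit.params
        for name in model.free_parameters:
            j = model.spec.parameters.index(name)
            h = 1e-5 * max(abs(k0[j]), 1.0)

            def peak_time(kj):
                k = k0.copy()
                k[j] = kj
                sol = find_entrained_orbit(model, k,
                                           x0_guess=forced_orbit.initial_state,
                                           pre_periods=0)
                ev = [e for e in detect_phase_events(sol, 0)
                      if e.kind == "peak"][0]
                return ev.time

            fd = (peak_time(k0[j] + h) - peak_time(k0[j] - h)) / (2 * h)
            assert pder[name] == pytest.approx(fd, rel=1e-3, abs=1e-6)

    def test_absent_parameter_is_zero(self):
        spec = ModelSpec(
            name="relax2", variables=("x",), parameters=("a", "unused"),
            rhs=("-a*x + I",),
            forcings=(ForcingProfile(name="I", kind="square-wave", period=24.0,
                                     on_windows=((0.0, 12.0),)),))
        model = compile_model(spec)
        sol = find_entrained_orbit(model, [1.0, 9.9], x0_guess=[0.5])
        data = compute_step_matrices(model, sol)
        field = solution_derivatives(model, sol, data)
        event = [e for e in detect_phase_events(sol, 0) if e.kind == "peak"][0]
        pder = phase_derivatives(model, sol, field, event)
        assert pder["unused"] == pytest.approx(0.0, abs=1e-12)

    def test_autonomous_solution_rejected(self, lam_model, lam_cycle, lam_var):
        model, _, _ = lam_model
        _, field = lam_var
        ev = detect_phase_events(lam_cycle, 0)[0]
        with pytest.raises(AnalysisError, match="forced"):
            phase_derivatives(model, lam_cycle, field, ev)


@pytest.fixture(scope="module")
def event_and_pircs(forced_model, forced_orbit, forced_var):
    model, _, _ = forced_model
    data, _ = forced_var
    event = [e for e in detect_phase_events(forced_orbit, 0)
             if e.kind == "peak"][0]
    return event, phase_irc(model, forced_orbit, data, event)


class TestPhaseIRC:
    def test_integral_plus_point_equals_phase_derivative(
            self, forced_model, forced_orbit, forced_var, event_and_pircs):
        model, _, _ = forced_model
        _, field = forced_var
        event, pircs = event_and_pircs
        pder = phase_derivatives(model, forced_orbit, field, event)
        for q in pircs:
            assert -(q.signed_area + q.point_term) == pytest.approx(
                pder[q.parameter], abs=1e-6 * max(1.0, abs(pder[q.parameter])))

    def test_pulse_oracle(self, forced_model, forced_orbit, event_and_pircs):
        """A pulse repeated each cycle over a window away from the peak
        shifts the peak by -dk times the advance-curve area (5 %)."""
        model, params, _ = forced_model
        event, pircs = event_and_pircs
        dk = 1e-3
        phi1, phi2 = 8.0, 11.0
        assert not (phi1 <= event.time <= phi2)
        q = [p for p in pircs if p.parameter == "b"][0]
        mask = (q.phi >= phi1) & (q.phi <= phi2)
        area = np.trapezoid(q.curve[mask], q.phi[mask])

        spec, base_params, _ = fixture("goodwin_forced")
        pulsed_spec = ModelSpec(
            name="gf_pulsed", variables=spec.variables,
            parameters=spec.parameters + ("db",),
            rhs=tuple(e.replace("b*x", "(b + db*P)*x") for e in spec.rhs),
            forcings=spec.forcings + (
                ForcingProfile(name="P", kind="pulse-train", period=24.0,
                               on_windows=((phi1, phi2),)),),
            fixed_parameters=spec.fixed_parameters)
        pulsed = compile_model(pulsed_spec)
        k = dict(base_params)
        k["db"] = dk
        sol = find_entrained_orbit(pulsed, k, x0_guess=forced_orbit.initial_state,
                                   pre_periods=5)
        ev = [e for e in detect_phase_events(sol, 0) if e.kind == "peak"][0]
        shift = ev.time - event.time
        assert shift == pytest.approx(-dk * area, rel=0.05)

    def test_discontinuity_at_event(self, event_and_pircs):
        """The curve jumps where the impulse crosses the peak being timed:
        one-sided linear extrapolations to the event time disagree, while at
        a smooth interior point they agree."""
        event, pircs = event_and_pircs

        def extrapolation_gap(q, i):
            left = 2 * q.curve[i - 1] - q.curve[i - 2]
            right = 2 * q.curve[i] - q.curve[i + 1]
            return abs(right - left)

        q = max(pircs, key=lambda p: abs(p.signed_area))
        scale = np.abs(q.curve).max()
        i_event = int(np.searchsorted(q.phi, event.time))
        assert extrapolation_gap(q, i_event) > 0.05 * scale
        i_smooth = int(np.searchsorted(q.phi, event.time + 6.0))
        assert extrapolation_gap(q, i_smooth) < 0.01 * scale

    def test_absent_parameter_zero(self, forced_orbit):
        spec, base_params, _ = fixture("goodwin_forced")
        padded = ModelSpec(name="gf_pad", variables=spec.variables,
                           parameters=spec.parameters + ("unused",),
                           rhs=spec.rhs, forcings=spec.forcings,
                           fixed_parameters=spec.fixed_parameters)
        model = compile_model(padded)
        k = dict(base_params)
        k["unused"] = 1.0
        sol = find_entrained_orbit(model, k, x0_guess=forced_orbit.initial_state,
                                   pre_periods=0)
        data = compute_step_matrices(model, sol)
        event = [e for e in detect_phase_events(sol, 0) if e.kind == "peak"][0]
        q = phase_irc(model, sol, data, event, "unused")
        assert np.abs(q.curve).max() == 0.0 and q.point_term == 0.0


class TestClassicalCoefficients:
    def test_value_observable_closed_form(self):
        spec = ModelSpec(name="step", variables=("x",),
                         parameters=("k1", "k2"), rhs=("k1 - k2*x",))
        model = compile_model(spec)
        sol = simulate(model, [1.0, 1.0], [0.0], (0.0, 1.0), n_points=21)
        field = solution_derivatives(model, sol)
        C = classical_coefficient(("value", 0, 1.0), field, sol)
        assert C["k1"] == pytest.approx(1 - math.exp(-1.0), abs=1e-7)

    def test_period_observable_cross_check(self, goodwin_var, goodwin_cycle,
                                           goodwin_ircs):
        _, field = goodwin_var
        C = classical_coefficient(("period",), field, goodwin_cycle)
        pder = period_derivatives(goodwin_ircs)
        assert np.abs(C.to_numpy() - pder.to_numpy()).max() <= 1e-6

    def test_amplitude_of_constant_variable_is_zero(self):
        spec = ModelSpec(
            name="flat", variables=("x", "c"), parameters=("a",),
            rhs=("-a*x + I", "a*(1 - c)"),
            forcings=(ForcingProfile(name="I", kind="square-wave", period=24.0,
                                     on_windows=((0.0, 12.0),)),))
        model = compile_model(spec)
        sol = find_entrained_orbit(model, [1.0], x0_guess=[0.5, 1.0])
        data = compute_step_matrices(model, sol)
        field = solution_derivatives(model, sol, data)
        C = classical_coefficient(("amplitude", 1), field, sol)
        assert np.abs(C.to_numpy()).max() == 0.0

    def test_unknown_observable_rejected(self, goodwin_var, goodwin_cycle):
        _, field = goodwin_var
        with pytest.raises(AnalysisError, match="unknown"):
            classical_coefficient(("entropy",), field, goodwin_cycle)
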