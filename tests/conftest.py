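"""Shared, session-scoped fixtures: compiled models and solved orbits.

The expensive objects (refined limit cycles, entrained orbits, variational
data, sensitivity fields) are computed once per session and shared; tests
must not mutate them except through the documented fill-in operations
(rescale_derivatives).
"""

import numpy as np
import pytest

from oscsens.fixtures import fixture_compiled
from oscsens.trajectory import (find_entrained_orbit,
                                find_limit_cycle_autonomous,
                                find_signalling_solution)
from oscsens.variational import compute_step_matrices, solution_derivatives


@pytest.fixture(scope="session")
def lam_model():
    model, params, ics = fixture_compiled("lambda_omega")
    return model, params, np.array([ics["x"], ics["y"]])


@pytest.fixture(scope="session")
def lam_cycle(lam_model):
    model, params, x0 = lam_model
    return find_limit_cycle_autonomous(model, params, x0, 1.0)


@pytest.fixture(scope="session")
def lam_var(lam_model, lam_cycle):
    model, _, _ = lam_model
    data = compute_step_matrices(model, lam_cycle)
    field = solution_derivatives(model, lam_cycle, data)
    return data, field


@pytest.fixture(scope="session")
def goodwin_model():
    model, params, ics = fixture_compiled("goodwin")
    return model, params, np.array([ics["x"], ics["y"], ics["z"]])


@pytest.fixture(scope="session")
def goodwin_cycle(goodwin_model):
    model, params, x0 = goodwin_model
    return find_limit_cycle_autonomous(model, params, x0, 30.0)


@pytest.fixture(scope="session")
def goodwin_var(goodwin_model, goodwin_cycle):
    model, _, _ = goodwin_model
    data = compute_step_matrices(model, goodwin_cycle)
    field = solution_derivatives(model, goodwin_cycle, data)
    return data, field


@pytest.fixture(scope="session")
def forced_model():
    model, params, ics = fixture_compiled("goodwin_forced")
    return model, params, np.array([ics["x"], ics["y"], ics["z"]])


@pytest.fixture(scope="session")
def forced_orbit(forced_model):
    model, params, x0 = forced_model
    return find_entrained_orbit(model, params, x0_guess=x0)


@pytest.fixture(scope="session")
def forced_var(forced_model, forced_orbit):
    model, _, _ = forced_model
    data = compute_step_matrices(model, forced_orbit)
    field = solution_derivatives(model, forced_orbit, data)
    return data, field


@pytest.fixture(scope="session")
def vdp_cycle():
    model, params, _ = fixture_compiled("van_der_pol")
    return model, find_limit_cycle_autonomous(model, params, [2.0, 0.0], 6.66)


@pytest.fixture(scope="session")
def cascade_solution():
    model, params, ics = fixture_compiled("cascade")
    stim = dict(params)
    stim["stim"] = 2.0
    sol = find_signalling_solution(model, params, stim, 20.0,
                                   x0_guess=[0.3, 0.3, 0.3])
    return model, sol
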