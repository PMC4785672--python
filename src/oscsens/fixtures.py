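"""Built-in fixture models with known analytic structure.

These small models exercise every analysis code path at desk scale:

* ``lambda_omega`` — the λ–ω normal-form oscillator.  In polar coordinates
  ṙ = r(1 - r²), θ̇ = ω: the unit circle is a limit cycle with period
  2π/ω, non-trivial Floquet multiplier e^{-2τ}, isochrons θ/ω, and
  dτ/dω = -2π/ω².  Every period/IRC quantity has a closed form.
* ``van_der_pol`` — the classic relaxation oscillator (μ = 1,
  τ ≈ 6.6632868593231 from high-accuracy integration).
* ``goodwin`` — a three-stage negative-feedback transcriptional oscillator
  (repression a/(1+z^h), Hill exponent h = 10 held fixed, linear decays).
  The shipped parameters put it on a confirmed limit cycle.
* ``goodwin_forced`` — the same loop with a 12:12 square wave multiplying
  transcription (period 24), modelling light entrainment of a circadian
  oscillator.
* ``cascade`` — a linear three-stage signalling chain with negative
  feedback and a stable unstimulated equilibrium; the stimulus parameter
  ``stim`` switches between unstimulated (0) and stimulated conditions.
"""

from __future__ import annotations

import math

from .model import ModelSpec, compile_model, parse_model_template

__all__ = ["FIXTURES", "fixture", "fixture_compiled"]

_TEMPLATES = {
    "lambda_omega": """
model lambda_omega
variables: x y
parameters: w
equations:
    dx/dt = x*(1 - x^2 - y^2) - w*y
    dy/dt = y*(1 - x^2 - y^2) + w*x
""",
    "van_der_pol": """
model van_der_pol
variables: x y
parameters: mu
equations:
    dx/dt = y
    dy/dt = mu*(1 - x^2)*y - x
""",
    "goodwin": """
model goodwin
variables: x y z
parameters: a b c d p q h
fixed: h
equations:
    dx/dt = a/(1 + z^h) - b*x
    dy/dt = c*x - d*y
    dz/dt = p*y - q*z
""",
    "goodwin_forced": """
model goodwin_forced
variables: x y z
parameters: a b c d p q h
fixed: h
equations:
    dx/dt = a*L/(1 + z^h) - b*x
    dy/dt = c*x - d*y
    dz/dt = p*y - q*z
forcings:
    L square-wave period=24.0 high=1.0 low=0.2 on=0.0:12.0
""",
    "cascade": """
model cascade
variables: x y z
parameters: b0 stim r d1 a2 d2 a3 d3
equations:
    dx/dt = b0 + stim - d1*x - r*z
    dy/dt = a2*x - d2*y
    dz/dt = a3*y - d3*z
""",
}

_GOODWIN_PARAMS = {"a": 1.0, "b": 0.2, "c": 1.0, "d": 0.2,
                   "p": 1.0, "q": 0.2, "h": 10.0}

_CATALOG = {
    "lambda_omega": {
        "params": {"w": 2 * math.pi},
        "ics": {"x": 1.0, "y": 0.0},
        "guess_period": 1.0,
        "kind": "autonomous-periodic",
        "facts": {"period": 1.0, "nontrivial_multiplier": math.exp(-2.0),
                  "dtau_dw": -1.0 / (2 * math.pi)},
    },
    "van_der_pol": {
        "params": {"mu": 1.0},
        "ics": {"x": 2.0, "y": 0.0},
        "guess_period": 6.66,
        "kind": "autonomous-periodic",
        "facts": {"period": 6.6632868593231},
    },
    "goodwin": {
        "params": dict(_GOODWIN_PARAMS),
        "ics": {"x": 0.5, "y": 2.0, "z": 2.0},
        "guess_period": 30.0,
        "kind": "autonomous-periodic",
        "facts": {},
    },
    "goodwin_forced": {
        "params": dict(_GOODWIN_PARAMS),
        "ics": {"x": 0.5, "y": 2.0, "z": 2.0},
        "guess_period": 24.0,
        "kind": "forced-periodic",
        "facts": {"forcing_period": 24.0},
    },
    "cascade": {
        "params": {"b0": 1.0, "stim": 0.0, "r": 2.0, "d1": 1.0,
                   "a2": 1.0, "d2": 1.0, "a3": 1.0, "d3": 1.0},
        "ics": {"x": 0.3, "y": 0.3, "z": 0.3},
        "stimulated": {"stim": 2.0},
        "kind": "transient",
        "facts": {},
    },
}

FIXTURES = tuple(sorted(_CATALOG))


def fixture(name: str):
    """Return ``(ModelSpec, params, ics)`` for a catalogued fixture model."""
    if name not in _CATALOG:
        raise KeyError(f"unknown fixture {name!r}; available: {list(FIXTURES)}")
    entry = _CATALOG[name]
    spec = parse_model_template(_TEMPLATES[name])
    return spec, dict(entry["params"]), dict(entry["ics"])


def fixture_compiled(name: str):
    """Compiled convenience variant: ``(CompiledModel, params, ics)``."""
    spec, params, ics = fixture(name)
    return compile_model(spec), params, ics


def fixture_info(name: str) -> dict:
    """Catalogue metadata (solution kind, period guess, analytic facts)."""
    if name not in _CATALOG:
        raise KeyError(f"unknown fixture {name!r}; available: {list(FIXTURES)}")
    return dict(_CATALOG[name])
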