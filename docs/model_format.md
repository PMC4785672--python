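# Model template format

Models are declared in a sectioned plain-text format with one assignment per
line.  `#` starts a comment.  Sections may appear in any order; `variables`,
`parameters` and `equations` are required.

```
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
```

* **model** — optional name line.
* **variables / parameters** — whitespace- or comma-separated name lists.
  Names must be unique across variables, parameters and forcings; `t` is
  reserved for time.
* **fixed** — parameters excluded from every sensitivity output (typically
  Hill exponents held at literature values).
* **equations** — one `d<var>/dt = expression` (or `<var>' = expression`) line
  per variable.  Expressions may use `+ - * / ^` (or `**`), parentheses, and
  the smooth functions `exp log sqrt sin cos tan tanh sinh cosh atan`.
  Non-smooth constructs (`Abs`, `sign`, `Piecewise`, …) are rejected at
  compile time — discontinuities enter only through forcings, so integrators
  can split time spans at the switch times.
* **forcings** — `NAME KIND key=value ...` per line.  Kinds:
  * `square-wave` / `pulse-train`: periodic with `period=`, `high=`, `low=`,
    and `on=` as comma-separated `start:end` half-open windows `[start, end)`
    within one period during which the value is `high`;
  * `constant`: `level=`.

  Windows are half-open so evaluation at a boundary is unambiguous:
  a 12:12 square wave with `on=0:12` is high at t = 0 and low at t = 12.

Every symbol used in an equation must be declared; parse errors name the
offending symbol and line.  `serialize_model_template` renders a spec back to
this format, and parse∘serialize is the identity.

Parameter values and initial conditions are supplied separately as
two-column `name,value` CSV tables (`read_value_table` /
`write_value_table`), or inline in pipeline YAML configs.
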