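"""YAML run-configuration loader and the small non-procedural rule dialect.

A config file describes a complete run: the space (built-in name + numeric
parameters, or metric component expressions for an abstract space), the
axiom, production rules in a text dialect, derivation count, seed and solver
options.  Rule successors in the dialect are L-string templates whose module
parameters may be arithmetic expressions of the predecessor's formal
parameters, e.g.::

    rules:
      - predecessor: "F(l)"
        successor: "F(l/3)+(60)F(l/3)-(120)F(l/3)+(60)F(l/3)"

Expressions are parsed with sympy (no host-language eval).  Procedural rules
(host callables) are the general mechanism in the library API; the dialect
covers the deterministic parametric subset.
"""

from __future__ import annotations

import math
import re
from typing import Dict, List, Optional

import sympy
import yaml

from .errors import ConfigError, SpaceError
from .lsystem import LString, ProductionRule, _matching_paren, _name_regex
from .spaces import (
    MetricSpace2D,
    PoincareHalfPlane,
    Space,
    distance_metric_space,
    make_surface,
    validate_space,
)

__all__ = ["load_config", "parse_rule", "space_from_config", "expr_function"]

_PRED_RE = re.compile(r"^\s*(\S+?)\s*(?:\(([^)]*)\))?\s*$")


_EXPR_ALLOWED = re.compile(r"^[0-9a-zA-Z_+\-*/(). ^,<>=!]*$")


def expr_function(expr: str, symbols=("p", "q")):
    """Compile an arithmetic expression of the given symbols via sympy.

    Character whitelist applied before sympify (no quotes, no dunders), so
    config expressions stay pure arithmetic.
    """
    if not _EXPR_ALLOWED.match(expr) or "__" in expr:
        raise ConfigError(f"disallowed characters in expression {expr!r}")
    try:
        syms = sympy.symbols(symbols)
        e = sympy.sympify(expr)
    except (sympy.SympifyError, TypeError, SyntaxError) as err:
        raise ConfigError(f"cannot parse expression {expr!r}: {err}") from err
    if not isinstance(e, sympy.Basic):
        raise ConfigError(f"expression {expr!r} is not arithmetic")
    free = e.free_symbols - set(syms)
    if free:
        raise ConfigError(f"unknown symbols {free} in expression {expr!r}")
    f = sympy.lambdify(syms, e, modules="math")
    return f


def parse_rule(spec: Dict) -> ProductionRule:
    """Build a ProductionRule from the config dialect.

    Keys: ``predecessor`` ("A" or "A(x,y)"), ``successor`` (template
    L-string), optional ``left``/``right`` (context module names) and
    ``condition`` (expression of the formal parameters).
    """
    m = _PRED_RE.match(str(spec.get("predecessor", "")))
    if not m:
        raise ConfigError(f"bad predecessor {spec.get('predecessor')!r}")
    name = m.group(1)
    pnames = [s.strip() for s in (m.group(2) or "").split(",") if s.strip()]
    template = str(spec.get("successor", ""))
    succ = _compile_successor(template, pnames)
    cond = None
    if spec.get("condition"):
        cf = expr_function(str(spec["condition"]), tuple(pnames) or ("_",))
        cond = (lambda *params: bool(cf(*params))) if pnames else (
            lambda *params: bool(cf(0))
        )
    return ProductionRule(
        name=name,
        successor=succ,
        arity=len(pnames) if pnames else None,
        left=spec.get("left"),
        right=spec.get("right"),
        condition=cond,
    )


def _compile_successor(template: str, pnames: List[str]):
    """Parse the successor template once; evaluate parameter expressions per
    application."""
    name_re = _name_regex()
    items = []  # (module name, [compiled param expressions])
    i, n = 0, len(template)
    while i < n:
        if template[i].isspace():
            i += 1
            continue
        m = name_re.match(template, i)
        if not m:
            raise ConfigError(f"bad successor template at {template[i:i+10]!r}")
        nm = m.group(0)
        i = m.end()
        exprs = []
        if i < n and template[i] == "(" and nm not in ("[", "]"):
            j = _matching_paren(template, i)
            inner = template[i + 1 : j]
            for tok in inner.split(","):
                exprs.append(expr_function(tok, tuple(pnames) or ("_",)))
            i = j + 1
        items.append((nm, exprs))

    def successor(*params, **_ctx):
        from .lsystem import ModuleSymbol

        args = params if pnames else (0,)
        return LString(
            [ModuleSymbol(nm, [f(*args) for f in exprs]) for nm, exprs in items]
        )

    return successor


def space_from_config(spec) -> Space:
    """Build a space: {"kind": name, ...params} or {"metric": {...}}."""
    if isinstance(spec, str):
        spec = {"kind": spec}
    if "metric" in spec:
        ms = spec["metric"]
        if isinstance(ms, str) and ms == "poincare":
            return PoincareHalfPlane()
        g11 = expr_function(str(ms.get("g11", "1")))
        g12 = expr_function(str(ms.get("g12", "0")))
        g22 = expr_function(str(ms.get("g22", "1")))
        bounds = spec.get("bounds", ((-10, 10), (-10, 10)))
        space = MetricSpace2D(g11, g12, g22, bounds=bounds,
                              periodic=tuple(spec.get("periodic", (False, False))))
        validate_space(space)
        return space
    if "kind" not in spec:
        raise ConfigError("space config needs 'kind' or 'metric'")
    kind = spec["kind"]
    params = {k: v for k, v in spec.items() if k not in ("kind",)}
    try:
        if kind == "distance_metric":
            return distance_metric_space(**params)
        return make_surface(kind, **params)
    except (SpaceError, TypeError) as e:
        raise ConfigError(f"bad space config {spec!r}: {e}") from e


def load_config(path_or_dict) -> Dict:
    """Load and validate a YAML run config into a normalised dict."""
    if isinstance(path_or_dict, dict):
        raw = path_or_dict
    else:
        with open(path_or_dict) as fh:
            raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ConfigError("config must be a mapping")
    out: Dict = {}
    if "axiom" not in raw:
        raise ConfigError("config needs an 'axiom'")
    out["axiom"] = LString(str(raw["axiom"]))
    out["rules"] = [parse_rule(r) for r in raw.get("rules", [])]
    out["space"] = space_from_config(raw["space"]) if "space" in raw else None
    out["steps"] = int(raw.get("steps", 0))
    stochastic = bool(raw.get("stochastic", False))
    if stochastic and "seed" not in raw:
        raise ConfigError("stochastic programs require an explicit seed")
    out["seed"] = int(raw.get("seed", 0))
    out["ds"] = float(raw.get("ds", 0.01))
    out["default_angle"] = float(raw.get("default_angle", 90.0))
    out["bvp_method"] = str(raw.get("solver", "residual"))
    if out["bvp_method"] not in ("shoot", "residual"):
        raise ConfigError(f"unknown solver {out['bvp_method']!r}")
    u0 = raw.get("start")
    out["u0"] = None if u0 is None else tuple(map(float, u0))
    h0 = raw.get("heading")
    out["h0"] = None if h0 is None else tuple(map(float, h0))
    out["fields"] = {
        name: field_from_config(spec)
        for name, spec in (raw.get("fields") or {}).items()
    }
    return out


def field_from_config(spec):
    """Scalar field from an expression of (p, q) or a named built-in.

    Built-ins: ``{"builtin": "point_distance", "center": [x, y]}`` (Euclidean
    distance to a point) and ``{"builtin": "bumps", "amplitude": A}``
    (sinusoidal bump mixture ``A sin p sin q``).
    """
    from .fields import ScalarField

    if isinstance(spec, str):
        return ScalarField(expr_function(spec))
    if isinstance(spec, dict) and "builtin" in spec:
        kind = spec["builtin"]
        if kind == "point_distance":
            cx, cy = map(float, spec.get("center", (0.0, 0.0)))
            return ScalarField(lambda p, q: math.hypot(p - cx, q - cy))
        if kind == "bumps":
            A = float(spec.get("amplitude", 1.0))
            return ScalarField(lambda p, q: A * math.sin(p) * math.sin(q))
        raise ConfigError(f"unknown built-in field {kind!r}")
    raise ConfigError(f"bad field spec {spec!r}")
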