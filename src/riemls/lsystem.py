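"""Parametric, context-sensitive, bracketed L-systems.

An L-string is an ordered sequence of parameterised modules with well-formed
bracket nesting; brackets ``[`` / ``]`` delimit side branches.  Derivation
rewrites every module in parallel by its first matching production rule
(identity for unmatched modules).  Interpretation rules homomorphically map a
derived L-string onto turtle command modules, expanding depth-first.

Successors and conditions are host-language callables: a successor receives
the bound parameters positionally and, when the rule declares contexts, the
matched context parameters as ``left=`` / ``right=`` keyword tuples.  A rule
marked ``stochastic=True`` additionally receives a seeded ``rng`` keyword
(:class:`numpy.random.Generator`), which makes derivations reproducible.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Callable, Iterable, Optional, Sequence, Union

import numpy as np

from .errors import DepthError, StructuralError

__all__ = [
    "ModuleSymbol",
    "LString",
    "ProductionRule",
    "InterpretationRule",
    "derive",
    "match_context",
    "interpret_string",
    "fill_query_modules",
    "QUERY_NAMES",
]

#: Query modules filled in by an interpretation pass (turtle position,
#: heading, up vector, full captured state).
QUERY_NAMES = frozenset({"?P", "?H", "?U", "?T"})

_NUM_RE = re.compile(r"[-+]?(\d+\.?\d*|\.\d+)([eE][-+]?\d+)?")

#: Multi-character module names the parser recognises.  L-system notation
#: writes adjacent single-letter modules without separators ("AB" is A then
#: B), so long names must be registered; turtle commands are pre-registered
#: and user programs may add their own via :func:`register_module_name`.
LONG_NAMES = {
    "LineTo", "LineToShoot", "SetSpace", "EndSpace",
    "StartIndirect", "StopIndirect", "StaticF",
    "PTReset", "PTArrow",
    "StartBSpline", "BSplinePoint", "EndBSpline",
}


def register_module_name(name: str):
    """Make a multi-character module name parseable in L-string notation."""
    LONG_NAMES.add(name)


def _name_regex():
    longs = sorted(LONG_NAMES, key=len, reverse=True)
    alts = "|".join(re.escape(n) for n in longs)
    return re.compile(rf"\?[A-Za-z]+|{alts}|[A-Za-z_]|[+\-\[\]{{}}&/!;.|]")


class ModuleSymbol:
    """A named module with an ordered parameter list.

    Parameters may be numbers, vectors, or opaque payloads (e.g. a captured
    turtle state stored by a ``?T`` query).  Instances are mutable so that
    query modules can be filled in place by an interpretation pass.
    """

    __slots__ = ("name", "params")

    def __init__(self, name: str, params: Iterable = ()):
        if not name:
            raise StructuralError("module name must be nonempty")
        self.name = name
        self.params = list(params)
        if name in ("[", "]") and self.params:
            raise StructuralError("bracket modules carry no parameters")

    def copy(self) -> "ModuleSymbol":
        return ModuleSymbol(self.name, list(self.params))

    def __eq__(self, other):
        if isinstance(other, str):
            return self.name == other and not self.params
        return (
            isinstance(other, ModuleSymbol)
            and self.name == other.name
            and len(self.params) == len(other.params)
            and all(_param_eq(a, b) for a, b in zip(self.params, other.params))
        )

    def __hash__(self):
        return hash(self.name)

    def __repr__(self):
        return f"ModuleSymbol({self.name!r}, {self.params!r})"

    def __str__(self):
        if not self.params:
            return self.name
        return f"{self.name}({','.join(_format_param(p) for p in self.params)})"


def _param_eq(a, b):
    try:
        return bool(np.all(np.asarray(a) == np.asarray(b)))
    except Exception:
        return a is b


def _format_param(p) -> str:
    if isinstance(p, (bool, np.bool_)):
        return str(bool(p))
    if isinstance(p, (int, np.integer)):
        return str(int(p))
    if isinstance(p, (float, np.floating)):
        return f"{float(p):.17g}"
    return str(p)


class LString:
    """An ordered sequence of :class:`ModuleSymbol` with balanced brackets."""

    __slots__ = ("modules",)

    def __init__(self, modules: Union[str, Iterable] = ()):
        if isinstance(modules, str):
            modules = _parse(modules)
        elif isinstance(modules, LString):
            modules = list(modules.modules)
        out = []
        for m in modules:
            if isinstance(m, str):
                out.extend(_parse(m))
            elif isinstance(m, ModuleSymbol):
                out.append(m)
            elif isinstance(m, LString):
                out.extend(m.modules)
            else:
                raise StructuralError(f"cannot build LString from {m!r}")
        self.modules = out
        self._check_balance()

    def _check_balance(self):
        depth = 0
        for m in self.modules:
            if m.name == "[":
                depth += 1
            elif m.name == "]":
                depth -= 1
                if depth < 0:
                    raise StructuralError("unbalanced brackets: ']' before '['")
        if depth != 0:
            raise StructuralError("unbalanced brackets: unclosed '['")

    # -- sequence protocol -------------------------------------------------
    def __len__(self):
        return len(self.modules)

    def __iter__(self):
        return iter(self.modules)

    def __getitem__(self, i):
        return self.modules[i]

    def __add__(self, other):
        other = other if isinstance(other, LString) else LString(other)
        s = LString.__new__(LString)
        s.modules = self.modules + other.modules
        return s

    def __eq__(self, other):
        if isinstance(other, str):
            other = LString(other)
        return isinstance(other, LString) and self.modules == other.modules

    def __str__(self):
        return "".join(str(m) for m in self.modules)

    def __repr__(self):
        return f"LString({str(self)!r})"

    def matching_bracket(self, i: int) -> int:
        """Index of the ``]`` matching the ``[`` at index *i*."""
        depth = 0
        for j in range(i, len(self.modules)):
            if self.modules[j].name == "[":
                depth += 1
            elif self.modules[j].name == "]":
                depth -= 1
                if depth == 0:
                    return j
        raise StructuralError("no matching ']'")


def _parse(text: str) -> list:
    """Parse the plain-text notation ``Name(p1,p2)...`` with literal brackets."""
    out = []
    name_re = _name_regex()
    i, n = 0, len(text)
    while i < n:
        c = text[i]
        if c.isspace():
            i += 1
            continue
        m = name_re.match(text, i)
        if not m:
            raise StructuralError(f"cannot parse module at {text[i:i+12]!r}")
        name = m.group(0)
        i = m.end()
        params: list = []
        if i < n and text[i] == "(" and name not in ("[", "]"):
            j = _matching_paren(text, i)
            inner = text[i + 1 : j]
            if inner.strip():
                for tok in _split_args(inner):
                    params.append(_parse_param(tok))
            i = j + 1
        out.append(ModuleSymbol(name, params))
    return out


def _matching_paren(text, i):
    depth = 0
    for j in range(i, len(text)):
        if text[j] == "(":
            depth += 1
        elif text[j] == ")":
            depth -= 1
            if depth == 0:
                return j
    raise StructuralError("unclosed '(' in module parameters")


def _split_args(inner):
    args, depth, start = [], 0, 0
    for j, c in enumerate(inner):
        if c == "(":
            depth += 1
        elif c == ")":
            depth -= 1
        elif c == "," and depth == 0:
            args.append(inner[start:j])
            start = j + 1
    args.append(inner[start:])
    return [a.strip() for a in args]


def _parse_param(tok: str):
    m = _NUM_RE.fullmatch(tok)
    if m:
        f = float(tok)
        if f.is_integer() and ("." not in tok and "e" not in tok.lower()):
            return int(tok)
        return f
    if tok in ("True", "False"):
        return tok == "True"
    return tok  # opaque string payload


# ---------------------------------------------------------------------------
# Rules


@dataclass
class ContextPattern:
    """A single-module context pattern: module name plus captured arity.

    ``arity=None`` matches any parameter count; matched parameters are bound
    and exposed to the rule condition and successor.
    """

    name: str
    arity: Optional[int] = None

    def matches(self, mod: ModuleSymbol) -> bool:
        return mod.name == self.name and (
            self.arity is None or len(mod.params) == self.arity
        )


def _as_pattern(p) -> Optional[ContextPattern]:
    if p is None or isinstance(p, ContextPattern):
        return p
    return ContextPattern(str(p))


@dataclass
class ProductionRule:
    """``left < name(params) > right : condition -> successor``.

    ``successor`` is a callable returning an :class:`LString`, a list of
    modules, a plain-text fragment, or ``None`` (erasure); a constant
    string/LString successor is also accepted.  Brackets never appear as
    predecessors (they always map to themselves).
    """

    name: str
    successor: Union[Callable, str, LString, None]
    arity: Optional[int] = None
    left: Optional[Union[str, ContextPattern]] = None
    right: Optional[Union[str, ContextPattern]] = None
    condition: Optional[Callable] = None
    stochastic: bool = False

    def __post_init__(self):
        if self.name in ("[", "]"):
            raise StructuralError("brackets cannot be rewritten")
        self.left = _as_pattern(self.left)
        self.right = _as_pattern(self.right)

    def _ctx_kwargs(self, bindings):
        kw = {}
        if self.left is not None:
            kw["left"] = bindings.get("left")
        if self.right is not None:
            kw["right"] = bindings.get("right")
        return kw

    def matches(self, s: "LString", i: int) -> Optional[dict]:
        mod = s[i]
        if mod.name != self.name:
            return None
        if self.arity is not None and len(mod.params) != self.arity:
            return None
        ok, bindings = match_context(s, i, self.left, self.right)
        if not ok:
            return None
        if self.condition is not None:
            if not self.condition(*mod.params, **self._ctx_kwargs(bindings)):
                return None
        return bindings

    def produce(self, mod: ModuleSymbol, bindings: dict, rng) -> list:
        succ = self.successor
        if callable(succ):
            kw = self._ctx_kwargs(bindings)
            if self.stochastic:
                kw["rng"] = rng
            succ = succ(*mod.params, **kw)
        if succ is None:
            return []
        try:
            frag = succ if isinstance(succ, LString) else LString(succ)
        except StructuralError as e:
            raise StructuralError(
                f"rule for {self.name!r} produced a malformed fragment: {e}"
            ) from e
        return list(frag.modules)


@dataclass
class InterpretationRule(ProductionRule):
    """Context-free rule translating modules into turtle commands; may recurse."""

    def __post_init__(self):
        super().__post_init__()
        if self.left is not None or self.right is not None:
            raise StructuralError("interpretation rules are context-free")


# ---------------------------------------------------------------------------
# Context matching


def match_context(s: LString, index: int, left_pattern=None, right_pattern=None):
    """Match single-module left/right contexts around ``s[index]``.

    The left context skips over complete bracketed side branches, and the left
    context of the first module inside a branch is the module preceding the
    ``[``.  The right context may either descend into a following branch or
    skip complete branches.  Returns ``(ok, bindings)`` where bindings maps
    ``"left"``/``"right"`` to the matched module's parameter tuple.
    """
    left_pattern = _as_pattern(left_pattern)
    right_pattern = _as_pattern(right_pattern)
    bindings: dict = {}

    if left_pattern is not None:
        j = index - 1
        found = None
        while j >= 0:
            name = s[j].name
            if name == "]":
                depth = 1
                j -= 1
                while j >= 0 and depth:
                    if s[j].name == "]":
                        depth += 1
                    elif s[j].name == "[":
                        depth -= 1
                    j -= 1
            elif name == "[":
                j -= 1  # climbing out of our own branch: parent module is next
            else:
                found = s[j]
                break
        if found is None or not left_pattern.matches(found):
            return False, {}
        bindings["left"] = tuple(found.params)

    if right_pattern is not None:
        candidates = []
        j = index + 1
        while j < len(s):
            name = s[j].name
            if name == "]":
                break  # end of our branch: nothing follows
            if name == "[":
                k = s.matching_bracket(j)
                if j + 1 <= k - 1:
                    candidates.append(s[j + 1])  # first module inside branch
                j = k + 1  # and also consider skipping the branch
            else:
                candidates.append(s[j])
                break
        matched = next((c for c in candidates if right_pattern.matches(c)), None)
        if matched is None:
            return False, {}
        bindings["right"] = tuple(matched.params)

    return True, bindings


# ---------------------------------------------------------------------------
# Derivation and interpretation


def derive(
    s: LString,
    rules: Sequence[ProductionRule],
    steps: int = 1,
    rng_seed: int = 0,
    rng: Optional[np.random.Generator] = None,
) -> LString:
    """Parallel rewriting: apply the first matching rule to every module.

    Unmatched modules (including brackets) are copied unchanged.  Ties between
    rules are resolved by declaration order.  ``rng_seed`` seeds the generator
    handed to stochastic successors, making derivations bit-reproducible
    (pass an explicit ``rng`` to continue an existing stream).
    """
    s = s if isinstance(s, LString) else LString(s)
    if rng is None:
        rng = np.random.default_rng(rng_seed)
    for _ in range(steps):
        out = []
        for i, mod in enumerate(s.modules):
            if mod.name in ("[", "]"):
                out.append(mod)
                continue
            for rule in rules:
                bindings = rule.matches(s, i)
                if bindings is not None:
                    out.append(rule.produce(mod, bindings, rng))
                    break
            else:
                out.append(mod)
        flat = []
        for item in out:
            if isinstance(item, list):
                flat.extend(item)
            else:
                flat.append(item)
        nxt = LString.__new__(LString)
        nxt.modules = flat
        nxt._check_balance()
        s = nxt
    return s


def interpret_string(
    s: LString,
    irules: Sequence[InterpretationRule],
    max_depth: int = 64,
    keep: Optional[frozenset] = None,
) -> LString:
    """Homomorphic depth-first expansion of *s* into turtle command modules.

    Each module is replaced by its interpretation image, recursively expanded
    before moving on.  Modules with no rule are kept when their name is in
    *keep* (by default: any module without a rule is kept if it is a bracket,
    a query module, or a known turtle command — callers pass the command set);
    with an explicit *keep* set, unmatched modules outside it are dropped.
    """
    s = s if isinstance(s, LString) else LString(s)
    out: list = []

    def expand(mod: ModuleSymbol, depth: int):
        if mod.name in ("[", "]"):
            out.append(mod)
            return
        for rule in irules:
            if mod.name == rule.name and (
                rule.arity is None or len(mod.params) == rule.arity
            ):
                if rule.condition is not None and not rule.condition(*mod.params):
                    continue
                if depth >= max_depth:
                    raise DepthError(
                        f"interpretation of {rule.name!r} exceeded depth {max_depth}"
                    )
                for sub in rule.produce(mod, {}, None):
                    expand(sub, depth + 1)
                return
        if keep is None or mod.name in keep or mod.name in QUERY_NAMES:
            out.append(mod)

    for mod in s.modules:
        expand(mod, 0)
    res = LString.__new__(LString)
    res.modules = out
    res._check_balance()
    return res


def fill_query_modules(
    s: LString,
    interpreter,
    irules: Sequence[InterpretationRule] = (),
    max_depth: int = 64,
) -> LString:
    """Run one interpretation pass to fill ``?P``/``?H``/``?U``/``?T`` modules.

    The string is interpreted into turtle commands (query modules pass
    through by reference) and executed by *interpreter* (a Riemannian turtle);
    on reaching a query module the turtle writes its current position /
    heading / up vector / captured state into the module's parameters in
    place, so the filled values are visible to productions at the next
    derivation.  Returns *s* (mutated in place).
    """
    commands = interpret_string(s, irules, max_depth=max_depth,
                                keep=getattr(interpreter, "COMMANDS", None))
    interpreter.execute(commands)
    return s
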