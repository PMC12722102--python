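"""The Riemannian turtle: interprets command strings on a curved space.

The turtle state lives in parameter coordinates: position ``u = (p, q)`` and
heading ``h``, a tangent 2-vector kept at unit metric norm.  ``F`` moves
along a geodesic (initial-value integration), so the heading is parallel
transported by construction; ``+``/``-`` rotate the heading within the
tangent plane through a Gram–Schmidt orthonormal basis (positive angles turn
toward the turtle's left arm L, counterclockwise about the surface normal U).
The accumulated turn angle ``alpha_c`` since the last parallel-transport
reset lets ``PTArrow`` draw the parallel transport of a reference vector:
between turns the turtle follows geodesics, along which a transported vector
keeps a constant angle to the heading, so the transported direction is the
heading corrected by ``phi_t = phi_0 − alpha_c``.

Modes: *direct* (geodesic semantics), *indirect* (flat Euclidean semantics
in the uv parameter rectangle, segments pushed forward to the surface —
convected forms), and *euclidean* (after ``EndSpace``: a classical 3-D
turtle leaving the surface, seeded with the surface frame).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np

from . import geodesics as geo
from .errors import CacheError, ModeError, QueryError, StackError
from .lsystem import (
    InterpretationRule,
    LString,
    ModuleSymbol,
    ProductionRule,
    derive,
    fill_query_modules,
    interpret_string,
)
from .scene import Scene, SceneItem
from .spaces import ParametricSurface, Plane, Space

__all__ = ["TurtleState", "RiemannianTurtle", "LsystemProgram", "run", "default_start"]


def _rot(theta: float) -> np.ndarray:
    c, s = math.cos(theta), math.sin(theta)
    return np.array([[c, -s], [s, c]])


@dataclass
class TurtleState:
    u: np.ndarray
    h: np.ndarray
    alpha_c: float = 0.0
    mode: str = "direct"  # direct | indirect | euclidean
    width: float = 1.0
    color: int = 0
    # euclidean-mode 3-D state
    e_pos: Optional[np.ndarray] = None
    e_H: Optional[np.ndarray] = None
    e_L: Optional[np.ndarray] = None
    e_U: Optional[np.ndarray] = None

    def copy(self) -> "TurtleState":
        return TurtleState(
            u=self.u.copy(),
            h=self.h.copy(),
            alpha_c=self.alpha_c,
            mode=self.mode,
            width=self.width,
            color=self.color,
            e_pos=None if self.e_pos is None else self.e_pos.copy(),
            e_H=None if self.e_H is None else self.e_H.copy(),
            e_L=None if self.e_L is None else self.e_L.copy(),
            e_U=None if self.e_U is None else self.e_U.copy(),
        )


def default_start(space: Space) -> Tuple[np.ndarray, np.ndarray]:
    """A sensible interior start: domain midpoint (origin on open axes),
    heading along +p normalised to unit metric norm."""
    u = np.empty(2)
    for a in range(2):
        lo, hi = space.bounds[a]
        if math.isfinite(lo) and math.isfinite(hi):
            u[a] = 0.5 * (lo + hi)
        elif math.isfinite(lo):
            u[a] = lo + 1.0
        elif math.isfinite(hi):
            u[a] = hi - 1.0
        else:
            u[a] = 0.0
    h = np.array([1.0, 0.0])
    h = h / space.norm(u, h)
    return u, h


class RiemannianTurtle:
    """Executes turtle-command L-strings on a :class:`Space` into a Scene."""

    #: module names with built-in turtle meaning (used as the keep-set when
    #: interpreting L-strings)
    COMMANDS = frozenset(
        {
            "F", "f", "+", "-", "|", "[", "]", "!", ";",
            "?P", "?H", "?U", "?T",
            "LineTo", "LineToShoot", "EndSpace",
            "StartIndirect", "StopIndirect", "StaticF",
            "PTReset", "PTArrow",
            "StartBSpline", "BSplinePoint", "EndBSpline",
            "{", "}",
        }
    )

    def __init__(
        self,
        space: Optional[Space] = None,
        u0=None,
        h0=None,
        ds: float = geo.DS_DEFAULT,
        default_angle: float = 90.0,
        bvp_method: str = "residual",
        extra_commands: Optional[Dict[str, Callable]] = None,
        clip_boundary: bool = False,
    ):
        self.space = space if space is not None else Plane()
        if u0 is None or h0 is None:
            du, dh = default_start(self.space)
            u0 = du if u0 is None else np.asarray(u0, dtype=float)
            h0 = dh if h0 is None else np.asarray(h0, dtype=float)
        u0 = np.asarray(u0, dtype=float)
        h0 = np.asarray(h0, dtype=float)
        h0 = h0 / self.space.norm(self.space.wrap(u0), h0)
        self.state = TurtleState(u=u0, h=h0)
        self.stack: List[TurtleState] = []
        self.scene = Scene()
        self.ds = ds
        self.default_angle = default_angle
        self.bvp_method = bvp_method
        self.static_cache: Dict[str, tuple] = {}
        self.extra_commands = dict(extra_commands or {})
        self.clip_boundary = clip_boundary
        self._bspline_stack: List[tuple] = []
        self._polygon: Optional[List[np.ndarray]] = None

    # -- helpers --------------------------------------------------------------

    @property
    def embedded(self) -> bool:
        return self.space.is_embedded

    def _wrapped(self) -> np.ndarray:
        return self.space.wrap(self.state.u)

    def _record_path(self, path: geo.GeodesicPath):
        uv = path.u.copy()
        xyz = path.points3d() if self.embedded else None
        self.scene.add(
            SceneItem(
                "polyline", uv=uv, xyz=xyz,
                width=self.state.width, color=self.state.color,
                depth=len(self.stack),
            )
        )
        if self._polygon is not None:
            self._polygon.append(uv[-1])

    def _renorm(self):
        n = self.space.norm(self._wrapped(), self.state.h)
        self.state.h = self.state.h / n

    # -- space transitions ----------------------------------------------------

    def set_space(self, space: Space, u0=None, h0=None):
        """Enter direct mode on *space* at a configured start state."""
        self.space = space
        if u0 is None or h0 is None:
            du, dh = default_start(space)
            u0 = du if u0 is None else np.asarray(u0, dtype=float)
            h0 = dh if h0 is None else np.asarray(h0, dtype=float)
        self.state.u = np.asarray(u0, dtype=float)
        self.state.h = np.asarray(h0, dtype=float)
        self._renorm()
        self.state.mode = "direct"

    def end_space(self):
        """Leave the surface: switch to a classical 3-D Euclidean turtle
        seeded with the current position and surface frame."""
        if not self.embedded:
            raise ModeError("EndSpace needs an embedded space to escape into")
        st = self.state
        u = self._wrapped()
        J = self.space.jacobian(u)
        H = J @ st.h
        H = H / np.linalg.norm(H)
        U = self.space.normal(u)
        L = np.cross(U, H)
        st.e_pos = self.space.point(u)
        st.e_H, st.e_L, st.e_U = H, L, U
        st.mode = "euclidean"

    # -- motion ---------------------------------------------------------------

    def forward(self, l: float = 1.0, n_steps: Optional[int] = None, draw=True):
        st = self.state
        if st.mode == "euclidean":
            p0 = st.e_pos.copy()
            st.e_pos = p0 + l * st.e_H
            if draw:
                self.scene.add(
                    SceneItem("polyline", xyz=np.array([p0, st.e_pos]),
                              width=st.width, color=st.color,
                              depth=len(self.stack))
                )
            return
        if st.mode == "indirect":
            h = st.h / np.linalg.norm(st.h)
            u1 = st.u + l * h
            n = max(2, int(math.ceil(l / self.ds)) + 1)
            uv = st.u + np.linspace(0, 1, n)[:, None] * (u1 - st.u)
            if draw:
                xyz = (
                    np.array([self.space.point(self.space.wrap(q)) for q in uv])
                    if self.embedded else None
                )
                self.scene.add(
                    SceneItem("polyline", uv=uv.copy(), xyz=xyz,
                              width=st.width, color=st.color,
                              depth=len(self.stack))
                )
                if self._polygon is not None:
                    self._polygon.append(uv[-1])
            st.u, st.h = u1, h
            return
        try:
            path = geo.geodesic_ivp(
                self.space, st.u, st.h, l, n_steps=n_steps, ds=self.ds
            )
        except geo.BoundaryError as e:
            # optionally stop at the chart boundary instead of failing
            if not self.clip_boundary or getattr(e, "partial", None) is None \
                    or len(e.partial.u) < 2:
                raise
            path = e.partial
        if draw:
            self._record_path(path)
        st.u = path.u[-1]
        st.h = path.end_tangent
        self._renorm()
        return path

    def turn(self, angle_deg: Optional[float] = None, sign: float = 1.0):
        if angle_deg is None:
            angle_deg = self.default_angle
        theta = sign * math.radians(angle_deg)
        st = self.state
        if st.mode == "euclidean":
            H = math.cos(theta) * st.e_H + math.sin(theta) * st.e_L
            st.e_H = H / np.linalg.norm(H)
            st.e_L = np.cross(st.e_U, st.e_H)
            return
        if st.mode == "indirect":
            st.h = _rot(theta) @ st.h
            st.alpha_c += theta
            return
        B = self.space.orthonormal_basis(self._wrapped())
        comp = np.linalg.solve(B, st.h)
        st.h = B @ (_rot(theta) @ comp)
        st.alpha_c += theta
        self._renorm()

    def line_to(self, target, method: Optional[str] = None, draw=True):
        """Geodesic BVP move to a target parameter point (log-map heading)."""
        st = self.state
        if st.mode != "direct":
            raise ModeError("LineTo requires direct mode")
        method = method or self.bvp_method
        if method == "shoot":
            path = geo.geodesic_bvp_shoot(self.space, st.u, target, ds=self.ds)
        else:
            path = geo.geodesic_bvp_residual(self.space, st.u, target)
        # the implicit rotation onto the log-map direction is a turn: record
        # it in alpha_c so parallel-transport bookkeeping stays valid
        B = self.space.orthonormal_basis(self._wrapped())
        a = np.linalg.solve(B, st.h)
        b = np.linalg.solve(B, path.start_tangent)
        st.alpha_c += math.atan2(a[0] * b[1] - a[1] * b[0], a @ b)
        if draw:
            self._record_path(path)
        st.u = path.u[-1]
        st.h = path.end_tangent
        self._renorm()
        return path

    def static_forward(self, key, l: float):
        """Like F, but the geodesic's uv samples are computed once per key and
        replayed thereafter (re-pushed through the possibly modified surface)."""
        st = self.state
        if st.mode != "direct":
            raise ModeError("StaticF requires direct mode")
        key = str(key)
        if key in self.static_cache:
            l_cached, uv, vend = self.static_cache[key]
            if abs(l_cached - l) > 1e-12:
                raise CacheError(
                    f"StaticF key {key!r} reused with length {l} != {l_cached}"
                )
            xyz = (
                np.array([self.space.point(self.space.wrap(q)) for q in uv])
                if self.embedded else None
            )
            self.scene.add(
                SceneItem("polyline", uv=uv.copy(), xyz=xyz,
                          width=st.width, color=st.color, depth=len(self.stack))
            )
            st.u = uv[-1].copy()
            st.h = vend.copy()
            self._renorm()
        else:
            path = self.forward(l)
            self.static_cache[key] = (l, path.u.copy(), path.v[-1].copy())

    # -- parallel transport ----------------------------------------------------

    def parallel_transport_reset(self):
        self.state.alpha_c = 0.0

    def transported_arrow(self, vect_angle_deg: float = 0.0, vect_size: float = 0.2):
        """Draw the parallel transport of the reset-time reference vector.

        The drawn direction makes the angle ``phi_t = phi_0 − alpha_c`` with
        the current heading; valid because the segments between turns are
        geodesics (transport preserves the angle to the geodesic tangent).
        """
        st = self.state
        if st.mode == "euclidean":
            raise ModeError("PTArrow requires an active space")
        phi_t = math.radians(vect_angle_deg) - st.alpha_c
        u = self._wrapped()
        B = self.space.orthonormal_basis(u)
        comp = np.linalg.solve(B, st.h)
        comp = comp / np.linalg.norm(comp)
        d = B @ (_rot(phi_t) @ comp)  # unit metric norm
        uv = np.array([st.u, st.u + vect_size * d])
        xyz = None
        if self.embedded:
            P = self.space.point(u)
            D = self.space.pushforward(u, d)
            D = D / np.linalg.norm(D)
            xyz = np.array([P, P + vect_size * D])
        item = SceneItem("arrow", uv=uv, xyz=xyz, width=st.width,
                         color=st.color, depth=len(self.stack))
        self.scene.add(item)
        return item

    # -- indirect interpretation ------------------------------------------------

    def indirect_begin(self):
        if not self.embedded:
            raise ModeError("indirect interpretation needs an embedded space")
        if self.state.mode == "indirect":
            raise ModeError("indirect interpretation already active")
        self.state.mode = "indirect"
        n = np.linalg.norm(self.state.h)
        self.state.h = self.state.h / n

    def indirect_end(self):
        if self.state.mode != "indirect":
            raise ModeError("StopIndirect without StartIndirect")
        self.state.mode = "direct"
        self._renorm()

    # -- stack -------------------------------------------------------------------

    def push(self):
        self.stack.append(self.state.copy())

    def pop(self):
        if not self.stack:
            raise StackError("pop on empty turtle stack")
        self.state = self.stack.pop()

    # -- queries -------------------------------------------------------------------

    def _fill_query(self, mod: ModuleSymbol):
        st = self.state
        if st.mode == "euclidean" and mod.name != "?T":
            raise QueryError(f"{mod.name} outside an active space context")
        if mod.name == "?P":
            mod.params = [float(st.u[0]), float(st.u[1])]
        elif mod.name == "?H":
            mod.params = [float(st.h[0]), float(st.h[1])]
        elif mod.name == "?U":
            if not self.embedded:
                raise QueryError("?U needs an embedded space (surface normal)")
            n = self.space.normal(self._wrapped())
            mod.params = [float(n[0]), float(n[1]), float(n[2])]
        elif mod.name == "?T":
            captured = self.state.copy()
            mod.params = [CapturedState(captured, self.space)]

    # -- geodesic B-spline collection ------------------------------------------------

    def _bspline_begin(self, degree: int = 3):
        self._bspline_stack.append((int(degree), []))

    def _bspline_point(self):
        if not self._bspline_stack:
            raise ModeError("BSplinePoint outside StartBSpline/EndBSpline")
        self._bspline_stack[-1][1].append(self.state.u.copy())

    def _bspline_end(self, n_subdiv: int = 5):
        from .curves import ControlPolygon, subdivide

        if not self._bspline_stack:
            raise ModeError("EndBSpline without StartBSpline")
        degree, pts = self._bspline_stack.pop()
        poly = ControlPolygon(np.array(pts), closed=False, degree=degree)
        out = subdivide(self.space, poly, degree=degree, n_steps=n_subdiv)
        uv = out.points
        xyz = (
            np.array([self.space.point(self.space.wrap(q)) for q in uv])
            if self.embedded else None
        )
        self.scene.add(
            SceneItem("polyline", uv=uv, xyz=xyz, width=self.state.width,
                      color=self.state.color, depth=len(self.stack))
        )

    # -- execution --------------------------------------------------------------------

    def execute(self, s: LString) -> Scene:
        """Interpret a turtle-command string, appending to the scene."""
        s = s if isinstance(s, LString) else LString(s)
        for mod in s:
            name = mod.name
            p = mod.params
            if name == "F":
                self.forward(*(p or [1.0]))
            elif name == "f":
                self.forward(*(p or [1.0]), draw=False)
            elif name == "+":
                self.turn(p[0] if p else None, sign=+1.0)
            elif name == "-":
                self.turn(p[0] if p else None, sign=-1.0)
            elif name == "|":
                self.turn(180.0, sign=+1.0)
            elif name == "[":
                self.push()
            elif name == "]":
                self.pop()
            elif name == "!":
                self.state.width = float(p[0]) if p else 1.0
            elif name == ";":
                self.state.color = int(p[0]) if p else 0
            elif name in ("LineTo", "LineToShoot"):
                method = "shoot" if name == "LineToShoot" else None
                self.line_to((float(p[0]), float(p[1])), method=method)
            elif name == "EndSpace":
                self.end_space()
            elif name == "StartIndirect":
                self.indirect_begin()
            elif name == "StopIndirect":
                self.indirect_end()
            elif name == "StaticF":
                self.static_forward(p[0], float(p[1]))
            elif name == "PTReset":
                self.parallel_transport_reset()
            elif name == "PTArrow":
                self.transported_arrow(*[float(x) for x in p])
            elif name == "StartBSpline":
                self._bspline_begin(*[int(x) for x in p] or [3])
            elif name == "BSplinePoint":
                self._bspline_point()
            elif name == "EndBSpline":
                self._bspline_end(*[int(x) for x in p])
            elif name == "{":
                self._polygon = [self.state.u.copy()]
            elif name == "}":
                if self._polygon and len(self._polygon) >= 2:
                    uv = np.array(self._polygon)
                    xyz = (
                        np.array([self.space.point(self.space.wrap(q)) for q in uv])
                        if self.embedded else None
                    )
                    self.scene.add(SceneItem("polygon", uv=uv, xyz=xyz,
                                             depth=len(self.stack)))
                self._polygon = None
            elif name in ("?P", "?H", "?U", "?T"):
                self._fill_query(mod)
            elif name in self.extra_commands:
                self.extra_commands[name](self, *p)
            # modules without turtle meaning are ignored
        return self.scene


@dataclass
class CapturedState:
    """Opaque payload stored by a ``?T`` query: full turtle state + space."""

    state: TurtleState
    space: Space

    def __str__(self):  # keeps L-string serialisation printable
        u = self.state.u
        return f"T<{u[0]:.6g};{u[1]:.6g}>"


# ---------------------------------------------------------------------------
# Program orchestration


@dataclass
class LsystemProgram:
    """Axiom + rules + space + derivation count: a complete runnable model."""

    axiom: LString
    rules: Sequence[ProductionRule] = ()
    irules: Sequence[InterpretationRule] = ()
    space: Optional[Space] = None
    steps: int = 0
    seed: int = 0
    u0: Optional[Sequence[float]] = None
    h0: Optional[Sequence[float]] = None
    ds: float = geo.DS_DEFAULT
    default_angle: float = 90.0
    bvp_method: str = "residual"
    extra_commands: Optional[Dict[str, Callable]] = None
    clip_boundary: bool = False
    name: str = ""

    def make_turtle(self) -> RiemannianTurtle:
        return RiemannianTurtle(
            space=self.space, u0=self.u0, h0=self.h0, ds=self.ds,
            default_angle=self.default_angle, bvp_method=self.bvp_method,
            extra_commands=self.extra_commands,
            clip_boundary=self.clip_boundary,
        )


def run(program: LsystemProgram, seed: Optional[int] = None):
    """Derive, resolve query modules (two-phase steps), interpret, draw.

    Returns ``(scene, final_lstring)``.  Deterministic under a fixed seed:
    the seed feeds stochastic production successors and any stochastic
    turtle commands registered by the program.
    """
    if seed is None:
        seed = program.seed
    rng = np.random.default_rng(seed)
    s = (
        program.axiom
        if isinstance(program.axiom, LString)
        else LString(program.axiom)
    )
    keep = RiemannianTurtle.COMMANDS | set(program.extra_commands or ())

    def query_pass(string):
        if any(m.name in ("?P", "?H", "?U", "?T") for m in string):
            t = program.make_turtle()
            t.COMMANDS = keep  # type: ignore[attr-defined]
            fill_query_modules(string, t, program.irules)

    query_pass(s)
    for _ in range(program.steps):
        s = derive(s, program.rules, steps=1, rng=rng)
        query_pass(s)
    commands = interpret_string(s, program.irules, keep=keep)
    turtle = program.make_turtle()
    turtle.rng = np.random.default_rng(seed + 1)  # for stochastic commands
    scene = turtle.execute(commands)
    return scene, s
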