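"""Deterministic example gallery: named programs covering the engine.

Each entry is a builder returning an :class:`LsystemProgram`; all stochastic
entries take their randomness from the program seed, so repeated runs are
byte-identical.  The catalogue spans flat-space classics (spiral, seeded
random walk, Koch curve, tree), geodesic structures on curved surfaces
(Koch on sphere/torus, trees, geodesic bands and fans, pin coiling,
leaf-vein construction by boundary-value laterals), parallel-transport
demonstrations (octant holonomy, the spherical square that fails to close),
field feedback (curvature-gated walks, self-avoiding trees, tropism
attractors) and abstract hyperbolic/distance-metric spaces.
"""

from __future__ import annotations

import math
from typing import Callable, Dict

import numpy as np

from .fields import ScalarField, SegmentStore, gated_random_step, tropism_step
from .lsystem import LString, ModuleSymbol, ProductionRule
from .spaces import (
    EggBox,
    Ellipsoid,
    Pin,
    Plane,
    PoincareHalfPlane,
    Pseudosphere,
    Sphere,
    Torus,
    distance_metric_space,
)
from .turtle import LsystemProgram, RiemannianTurtle, run

__all__ = ["gallery_list", "build", "GALLERY"]


def _koch_rule():
    return ProductionRule(
        "F",
        lambda l: f"F({l/3})+(60)F({l/3})-(120)F({l/3})+(60)F({l/3})",
        arity=1,
    )


def flat_spiral() -> LsystemProgram:
    """Archimedean-style spiral: segments grow while the heading turns."""
    rule = ProductionRule(
        "A", lambda n: f"F({n})+(20)A({n + 0.02})", arity=1
    )
    return LsystemProgram(
        axiom=LString("A(0.1)"), rules=[rule], space=Plane(), steps=40,
        name="flat_spiral",
    )


def flat_random_walk() -> LsystemProgram:
    """Seeded uniform-turn random walk on the plane."""
    rule = ProductionRule(
        "A",
        lambda rng: f"+({rng.uniform(-180.0, 180.0)})F(0.3)A",
        stochastic=True,
    )
    return LsystemProgram(
        axiom=LString("A"), rules=[rule], space=Plane(), steps=40, seed=7,
        name="flat_random_walk",
    )


def flat_koch() -> LsystemProgram:
    return LsystemProgram(
        axiom=LString("F(1)"), rules=[_koch_rule()], space=Plane(), steps=3,
        name="flat_koch",
    )


def flat_tree() -> LsystemProgram:
    rule = ProductionRule(
        "A",
        lambda l: f"F({l})[+(35)A({0.7 * l})][-(35)A({0.7 * l})]",
        arity=1,
    )
    return LsystemProgram(
        axiom=LString("A(1)"), rules=[rule], space=Plane(), steps=5,
        name="flat_tree",
    )


def sphere_koch() -> LsystemProgram:
    return LsystemProgram(
        axiom=LString("F(2)"), rules=[_koch_rule()], space=Sphere(1.0),
        steps=3, u0=(math.pi / 2, 0.0), h0=(0.3, 1.0), name="sphere_koch",
    )


def koch_torus() -> LsystemProgram:
    return LsystemProgram(
        axiom=LString("F(3)"), rules=[_koch_rule()], space=Torus(1.0, 0.3),
        steps=3, u0=(0.0, 0.5), h0=(1.0, 0.4), name="koch_torus",
    )


def _tree_program(space, u0, h0, name, l0=0.6, steps=4) -> LsystemProgram:
    rule = ProductionRule(
        "A",
        lambda l: f"F({l})[+(40)A({0.75 * l})][-(40)A({0.75 * l})]",
        arity=1,
    )
    return LsystemProgram(
        axiom=LString(f"A({l0})"), rules=[rule], space=space, steps=steps,
        u0=u0, h0=h0, name=name,
    )


def sphere_tree() -> LsystemProgram:
    return _tree_program(Sphere(1.0), (math.pi / 2, 0.0), (-1.0, 0.2),
                         "sphere_tree")


def pseudosphere_tree() -> LsystemProgram:
    prog = _tree_program(Pseudosphere(1.0), (0.5, 0.0), (1.0, 0.3),
                         "pseudosphere_tree", l0=0.35)
    prog.clip_boundary = True
    return prog


def torus_tree() -> LsystemProgram:
    return _tree_program(Torus(1.0, 0.3), (0.0, 0.0), (1.0, 0.3),
                         "torus_tree", l0=0.8)


def ellipsoid_bands() -> LsystemProgram:
    """A long geodesic on a prolate ellipsoid oscillates between the two
    colatitude caps allowed by Clairaut's relation (a band)."""
    return LsystemProgram(
        axiom=LString("F(20)"), space=Ellipsoid(1.0, 1.0, 1.6), steps=0,
        u0=(math.pi / 2, 0.0), h0=(0.35, 1.0), ds=0.02,
        name="ellipsoid_bands",
    )


def pseudosphere_fan() -> LsystemProgram:
    """Fan of geodesics from one point: initially parallel rays diverge on a
    negatively curved surface."""
    branches = "".join(f"[+({a})F(1.5)]" for a in range(-30, 31, 10))
    return LsystemProgram(
        axiom=LString(branches), space=Pseudosphere(1.0), steps=0,
        u0=(1.0, 0.0), h0=(1.0, 0.0), ds=0.02, clip_boundary=True,
        name="pseudosphere_fan",
    )


def pin_coiling() -> LsystemProgram:
    """Geodesic climbing a pin-shaped funnel: the Clairaut invariant exceeds
    the neck radius, so the path turns back and coils around the bulge."""
    return LsystemProgram(
        axiom=LString("F(25)"), space=Pin(1.0, 0.2, 2.0, 3.0), steps=0,
        u0=(-2.0, 0.0), h0=(1.0, 1.2), ds=0.02, clip_boundary=True,
        name="pin_coiling",
    )


def sphere_octant_holonomy() -> LsystemProgram:
    """Transported arrow around a geodesic octant triangle: three quarter
    great circles and three +90° turns; the arrow returns rotated by the
    enclosed curvature integral π/2."""
    sph = Sphere(1.0)
    # octant rotated so that neither vertices nor sides meet the chart poles
    c, s = math.cos(0.6), math.sin(0.6)
    v1 = np.array([c, 0.0, -s])
    v2 = np.array([0.0, 1.0, 0.0])
    u1 = np.array([math.acos(v1[2]), math.atan2(v1[1], v1[0]) % (2 * math.pi)])
    h0 = np.linalg.lstsq(sph.jacobian(u1), v2, rcond=None)[0]
    side = f"F({math.pi / 2:.17g})+(90)"
    axiom = LString("PTReset PTArrow(0,0.25)" + side * 3 + "PTArrow(0,0.25)")
    return LsystemProgram(
        axiom=axiom, space=sph, steps=0, u0=u1, h0=h0,
        name="sphere_octant_holonomy",
    )


def spherical_square() -> LsystemProgram:
    """A 'square' traced directly on the sphere (four +90° turns) fails to
    close; the same square drawn in indirect (uv) mode closes exactly."""
    direct = "F(1)+(90)F(1)+(90)F(1)+(90)F(1)"
    indirect = "StartIndirect F(1)+(90)F(1)+(90)F(1)+(90)F(1) StopIndirect"
    return LsystemProgram(
        axiom=LString(f"[{direct}]f(0.1)[{indirect}]"), space=Sphere(1.0),
        steps=0, u0=(math.pi / 2, 0.0), h0=(0.0, 1.0),
        name="spherical_square",
    )


def curvature_gated_walk() -> LsystemProgram:
    """Random walk on an egg-box surface restricted to K > 0 regions."""

    def walk(turtle, n):
        rng = getattr(turtle, "rng", np.random.default_rng(0))
        for _ in range(int(n)):
            gated_random_step(
                turtle, rng, ds=0.3,
                gate=lambda u, K: K > 0, max_tries=30,
            )

    return LsystemProgram(
        axiom=LString("W(60)"), space=EggBox(0.8), steps=0,
        u0=(math.pi / 2, math.pi / 2), h0=(1.0, 0.0), seed=5,
        extra_commands={"W": walk}, name="curvature_gated_walk",
    )


def self_avoiding_tree() -> LsystemProgram:
    """Branching structure on the sphere whose segments refuse to cross
    previously drawn segments (uv-space test with a spatial hash)."""
    space = Sphere(1.0)

    def grow(turtle, l):
        store = getattr(turtle, "_sa_store", None)
        if store is None:
            store = SegmentStore.for_space(turtle.space, cell=0.3)
            turtle._sa_store = store
        saved = turtle.state.copy()
        n_items = len(turtle.scene.items)
        path = turtle.forward(float(l))
        if store.intersects(
            path.u, tol=0.02,
            exclude_point=path.u[0], exclude_radius=0.05,
        ):
            turtle.state = saved
            del turtle.scene.items[n_items:]
        else:
            store.add_polyline(path.u)

    rule = ProductionRule(
        "A",
        lambda l: f"G({l})[+(50)A({0.8 * l})][-(50)A({0.8 * l})]",
        arity=1,
    )
    return LsystemProgram(
        axiom=LString("A(0.7)"), rules=[rule], space=space, steps=5,
        u0=(math.pi / 2, 0.0), h0=(-1.0, 0.0), seed=3,
        extra_commands={"G": grow}, name="self_avoiding_tree",
    )


def ellipsoid_tropism() -> LsystemProgram:
    """Trajectory on a prolate ellipsoid deflected toward the equator by a
    field sourced at the poles: an attractor band (η > 0) versus the free
    Clairaut band (η = 0)."""
    space = Ellipsoid(1.0, 1.0, 1.6)
    field = ScalarField(lambda p, q: -math.cos(p) ** 2)  # max at equator

    def trop(turtle, eta, n, ds):
        for _ in range(int(n)):
            tropism_step(turtle, field, float(eta), float(ds))

    return LsystemProgram(
        axiom=LString("T(2.0,120,0.1)"), space=space, steps=0,
        u0=(math.pi / 2, 0.0), h0=(0.5, 1.0),
        extra_commands={"T": trop}, name="ellipsoid_tropism",
    )


def poincare_fan() -> LsystemProgram:
    """Fan of geodesics from one point of the hyperbolic half-plane: every
    path is an arc of a circle centred on the x-axis (or a vertical line)."""
    branches = "".join(f"[+({a})F(2)]" for a in range(0, 360, 30))
    return LsystemProgram(
        axiom=LString(branches), space=PoincareHalfPlane(), steps=0,
        u0=(0.0, 1.0), h0=(1.0, 0.0), ds=0.02, name="poincare_fan",
    )


def poincare_tree() -> LsystemProgram:
    """Branching system interpreted in the hyperbolic half-plane: straight
    branches become circular arcs sagging toward the x-axis ('gravity')."""
    prog = _tree_program(PoincareHalfPlane(), (0.0, 1.0), (0.2, 1.0),
                         "poincare_tree", l0=0.5, steps=4)
    prog.ds = 0.02
    return prog


def shadow_tree() -> LsystemProgram:
    """Tree growing in a distance-sourced metric (inverse mode): branches
    bend away from the source point — shadow avoidance."""
    space = distance_metric_space(center=(2.0, 2.0), a=0.3, b=1.0,
                                  mode="inverse")
    prog = _tree_program(space, (0.0, 0.0), (0.0, 1.0), "shadow_tree",
                         l0=0.8, steps=4)
    prog.ds = 0.02
    return prog


def leaf_vein_bvp() -> LsystemProgram:
    """Leaf-vein construction: a midrib grown by forward geodesic steps,
    lateral veins attached as boundary-value geodesics to rim targets."""
    sph = Sphere(1.0)
    parts = []
    for k in range(4):
        q = 0.35 * (k + 1)
        off = 0.5 * math.sin(math.pi * (k + 1) / 5.0)
        parts.append(f"F(0.35)[LineTo({math.pi / 2 - off:.17g},{q:.17g})]")
        parts.append(f"[LineTo({math.pi / 2 + off:.17g},{q:.17g})]")
    return LsystemProgram(
        axiom=LString("".join(parts)), space=sph, steps=0,
        u0=(math.pi / 2, 0.0), h0=(0.0, 1.0), name="leaf_vein_bvp",
    )


GALLERY: Dict[str, Callable[[], LsystemProgram]] = {
    f.__name__: f
    for f in [
        flat_spiral, flat_random_walk, flat_koch, flat_tree,
        sphere_koch, koch_torus,
        sphere_tree, pseudosphere_tree, torus_tree,
        ellipsoid_bands, pseudosphere_fan, pin_coiling,
        sphere_octant_holonomy, spherical_square,
        curvature_gated_walk, self_avoiding_tree, ellipsoid_tropism,
        poincare_fan, poincare_tree, shadow_tree, leaf_vein_bvp,
    ]
}


def gallery_list():
    """Name → one-line description of every built-in program."""
    out = {}
    for name, fn in GALLERY.items():
        doc = (fn.__doc__ or "").strip()
        out[name] = doc.splitlines()[0] if doc else name.replace("_", " ")
    return out


def build(name: str) -> LsystemProgram:
    if name not in GALLERY:
        raise KeyError(f"unknown gallery program {name!r}; see gallery_list()")
    return GALLERY[name]()
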