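"""Scalar fields on a space, tropism, curvature-gated walks, self-avoidance.

The Riemannian gradient of a scalar field f raises the index of the
coordinate differential with the inverse metric, grad^i = g^{ij} ∂_j f, so
its metric inner product with any direction equals the directional
derivative.  Tropism deflects the turtle toward (or away from) the gradient
by imposing a geodesic curvature proportional to the misalignment angle:
over a step of length ds the turtle turns by δ = η·θ·ds (θ the signed angle
from heading to gradient, positive on the turtle's left) before moving.

Self-avoidance tests segment crossings in the uv parameter plane (exact for
immersed surfaces) with a uniform, periodicity-aware spatial hash.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Dict, List, Optional, Tuple

import numpy as np

from .errors import DegeneratePointError
from .spaces import ParametricSurface, Space

__all__ = [
    "ScalarField",
    "field_gradient",
    "tropism_step",
    "curvature_at",
    "gated_random_step",
    "SegmentStore",
    "segment_add",
    "segment_intersects",
]


class ScalarField:
    """A smooth real-valued function on a space's parameter domain.

    ``grad`` optionally supplies the analytic covariant components
    (∂f/∂p, ∂f/∂q); otherwise central differences with step ``h`` are used.
    """

    def __init__(self, value: Callable[[float, float], float],
                 grad: Optional[Callable] = None, h: float = 1e-6):
        self._value = value
        self._grad = grad
        self.h = h

    def value(self, u) -> float:
        return float(self._value(float(u[0]), float(u[1])))

    def covariant_gradient(self, u) -> np.ndarray:
        """(∂f/∂p, ∂f/∂q) — the lower-index differential."""
        p, q = float(u[0]), float(u[1])
        if self._grad is not None:
            return np.asarray(self._grad(p, q), dtype=float)
        h = self.h
        return np.array(
            [
                (self._value(p + h, q) - self._value(p - h, q)) / (2 * h),
                (self._value(p, q + h) - self._value(p, q - h)) / (2 * h),
            ]
        )

    def __call__(self, u) -> float:
        return self.value(u)


def field_gradient(space: Space, field: ScalarField, u) -> np.ndarray:
    """Riemannian gradient g^{ij} ∂_j f at u (upper-index tangent vector)."""
    u = space.wrap(np.asarray(u, dtype=float))
    df = field.covariant_gradient(u)
    return space.inverse_metric(u) @ df


def signed_angle_to(space: Space, u, h, target) -> float:
    """Signed angle from direction h to direction target in the tangent
    plane (positive counterclockwise, i.e. toward the turtle's left)."""
    B = space.orthonormal_basis(space.wrap(np.asarray(u, dtype=float)))
    a = np.linalg.solve(B, np.asarray(h, dtype=float))
    b = np.linalg.solve(B, np.asarray(target, dtype=float))
    return math.atan2(a[0] * b[1] - a[1] * b[0], a @ b)


def tropism_step(turtle, field: ScalarField, eta: float, ds: float):
    """One field-deflected step: turn by δ = η·θ·ds toward the gradient,
    then move forward by ds along a geodesic.

    θ is the signed angle between the heading and the Riemannian gradient at
    the current position.  A vanishing gradient (or η = 0) gives a pure
    geodesic step.  Assumes ds small enough that the imposed geodesic
    curvature is constant over the step.
    """
    st = turtle.state
    grad = field_gradient(turtle.space, field, st.u)
    gnorm = turtle.space.norm(turtle.space.wrap(st.u), grad)
    if eta != 0.0 and gnorm > 1e-12:
        theta = signed_angle_to(turtle.space, st.u, st.h, grad)
        delta = eta * theta * ds
        if delta != 0.0:
            turtle.turn(math.degrees(delta))
    return turtle.forward(ds)


def curvature_at(turtle):
    """(K, H, κ1, κ2, dir1, dir2) at the turtle position.

    Mean and principal curvatures require an embedded space; for abstract
    spaces they are returned as None.
    """
    space = turtle.space
    u = space.wrap(turtle.state.u)
    K = space.gaussian_curvature(u, clamp=True)
    if isinstance(space, ParametricSurface):
        k1, k2, d1, d2 = space.principal_curvatures(u)
        return K, space.mean_curvature(u), k1, k2, d1, d2
    return K, None, None, None, None, None


def gated_random_step(
    turtle,
    rng: np.random.Generator,
    ds: float,
    gate: Callable,
    max_tries: int = 20,
    angle_range: Tuple[float, float] = (-180.0, 180.0),
):
    """Random-walk step accepted only where the gate predicate holds.

    Draws a uniform turn angle, tentatively executes turn + forward, and
    accepts the first endpoint with ``gate(u_end, K_end) == True``; rejected
    trials are rolled back (state and scene).  Returns the accepted path, or
    ``None`` after ``max_tries`` refusals (the walker stays put).
    """
    space = turtle.space
    for _ in range(max_tries):
        angle = float(rng.uniform(*angle_range))
        saved = turtle.state.copy()
        n_items = len(turtle.scene.items)
        try:
            turtle.turn(angle)
            path = turtle.forward(ds)
        except Exception:
            turtle.state = saved
            del turtle.scene.items[n_items:]
            continue
        u_end = space.wrap(turtle.state.u)
        try:
            K_end = space.gaussian_curvature(u_end, clamp=True)
        except DegeneratePointError:
            K_end = float("nan")
        if gate(u_end, K_end):
            return path
        turtle.state = saved
        del turtle.scene.items[n_items:]
    return None


# ---------------------------------------------------------------------------
# Segment store (self-avoidance)


def _seg_seg_distance(p1, p2, q1, q2) -> float:
    """Euclidean distance between two 2-D segments (0 if they cross)."""
    d1 = _orient(q1, q2, p1)
    d2 = _orient(q1, q2, p2)
    d3 = _orient(p1, p2, q1)
    d4 = _orient(p1, p2, q2)
    if ((d1 > 0) != (d2 > 0)) and ((d3 > 0) != (d4 > 0)):
        return 0.0
    return min(
        _point_seg(p1, q1, q2),
        _point_seg(p2, q1, q2),
        _point_seg(q1, p1, p2),
        _point_seg(q2, p1, p2),
    )


def _orient(a, b, c) -> float:
    return (b[0] - a[0]) * (c[1] - a[1]) - (b[1] - a[1]) * (c[0] - a[0])


def _point_seg(p, a, b) -> float:
    ab = (b[0] - a[0], b[1] - a[1])
    ap = (p[0] - a[0], p[1] - a[1])
    denom = ab[0] * ab[0] + ab[1] * ab[1]
    t = 0.0 if denom == 0 else max(0.0, min(1.0, (ap[0] * ab[0] + ap[1] * ab[1]) / denom))
    dx = p[0] - (a[0] + t * ab[0])
    dy = p[1] - (a[1] + t * ab[1])
    return math.hypot(dx, dy)


class SegmentStore:
    """uv polylines in a uniform spatial hash over the parameter domain.

    ``periods`` gives the period per axis (None on aperiodic axes); stored
    and queried segments are compared under period shifts of ±1 so crossings
    across the seam are detected.
    """

    def __init__(self, cell: float = 0.25,
                 periods: Tuple[Optional[float], Optional[float]] = (None, None)):
        self.cell = float(cell)
        self.periods = periods
        self._cells: Dict[Tuple[int, int], List[int]] = {}
        self.segments: List[Tuple[np.ndarray, np.ndarray]] = []

    @classmethod
    def for_space(cls, space: Space, cell: float = 0.25) -> "SegmentStore":
        periods = tuple(
            (space.bounds[a][1] - space.bounds[a][0]) if space.periodic[a] else None
            for a in range(2)
        )
        finite = [p for p in periods if p is not None]
        if finite:
            # cell must divide the period exactly for wrapped hashing
            p = min(finite)
            cell = p / max(1, int(math.ceil(p / cell)))
        return cls(cell=cell, periods=periods)

    def _cell_range(self, a, b):
        lo = np.minimum(a, b)
        hi = np.maximum(a, b)
        i0, j0 = int(np.floor(lo[0] / self.cell)), int(np.floor(lo[1] / self.cell))
        i1, j1 = int(np.floor(hi[0] / self.cell)), int(np.floor(hi[1] / self.cell))
        for i in range(i0, i1 + 1):
            for j in range(j0, j1 + 1):
                yield (i, j)

    def add_polyline(self, uv: np.ndarray):
        uv = np.asarray(uv, dtype=float)
        for k in range(len(uv) - 1):
            idx = len(self.segments)
            self.segments.append((uv[k].copy(), uv[k + 1].copy()))
            for c in self._cell_range(uv[k], uv[k + 1]):
                self._cells.setdefault(self._wrap_cell(c), []).append(idx)

    def _shifts(self):
        xs = [0.0] if self.periods[0] is None else [-self.periods[0], 0.0, self.periods[0]]
        ys = [0.0] if self.periods[1] is None else [-self.periods[1], 0.0, self.periods[1]]
        return [(x, y) for x in xs for y in ys]

    def intersects(
        self,
        uv: np.ndarray,
        tol: float = 0.0,
        exclude_point=None,
        exclude_radius: float = 0.0,
    ) -> bool:
        """Does the query polyline cross (or approach within tol of) any
        stored segment?  Segments whose closest approach lies within
        ``exclude_radius`` of ``exclude_point`` (e.g. the branch point the
        query emanates from) are exempt."""
        uv = np.asarray(uv, dtype=float)
        pad = tol + self.cell
        for k in range(len(uv) - 1):
            a, b = uv[k], uv[k + 1]
            cand = set()
            lo = np.minimum(a, b) - pad
            hi = np.maximum(a, b) + pad
            for c in self._cell_range(lo, hi):
                cc = self._wrap_cell(c)
                cand.update(self._cells.get(cc, ()))
            for idx in cand:
                q1, q2 = self.segments[idx]
                for sx, sy in self._shifts():
                    qq1 = (q1[0] + sx, q1[1] + sy)
                    qq2 = (q2[0] + sx, q2[1] + sy)
                    d = _seg_seg_distance(a, b, qq1, qq2)
                    if d <= tol:
                        if exclude_point is not None and exclude_radius > 0:
                            # adjacency at the shared branch point is exempt
                            near = max(
                                _point_seg(exclude_point, a, b),
                                _point_seg(exclude_point, qq1, qq2),
                            )
                            if near <= exclude_radius:
                                continue
                        return True
        return False

    def _wrap_cell(self, c):
        i, j = c
        if self.periods[0] is not None:
            n = max(1, int(round(self.periods[0] / self.cell)))
            i = i % n
        if self.periods[1] is not None:
            n = max(1, int(round(self.periods[1] / self.cell)))
            j = j % n
        return (i, j)

def segment_add(store: SegmentStore, path) -> SegmentStore:
    """Add a path's uv polyline (a GeodesicPath or an (n, 2) array)."""
    uv = path.u if hasattr(path, "u") else np.asarray(path, dtype=float)
    store.add_polyline(uv)
    return store


def segment_intersects(store: SegmentStore, path, tol: float = 0.0,
                       exclude_point=None, exclude_radius: float = 0.0) -> bool:
    uv = path.u if hasattr(path, "u") else np.asarray(path, dtype=float)
    return store.intersects(uv, tol=tol, exclude_point=exclude_point,
                            exclude_radius=exclude_radius)
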