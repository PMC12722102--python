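"""Smooth curves on curved spaces via geodesic Lane–Riesenfeld subdivision.

Classical uniform B-spline subdivision alternates *duplication* and
*averaging* steps; in the midpoint form, one refinement step of degree d
inserts the midpoint of every edge and then runs d−1 rounds in which every
consecutive pair is replaced by its midpoint.  Here the Euclidean midpoint is
replaced by the **geodesic midpoint** — the point at equal geodesic distance
along the boundary-value geodesic joining the pair — which reduces to the
classical scheme in flat space.  The limit curve lives on the space; it is
not strictly a B-spline but inherits its smoothing behaviour (higher degree,
smoother curve).

Open polygons are handled with pinned endpoints (clamped ends): averaging
rounds act on the midpoint sequence and the original endpoints are
re-attached, so the curve starts and ends at the polygon's tips.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .errors import ConvergenceError
from .geodesics import GeodesicPath, geodesic_bvp_residual, path_length
from .spaces import Space

__all__ = ["ControlPolygon", "geodesic_midpoint", "subdivide"]


@dataclass
class ControlPolygon:
    points: np.ndarray  # (n, 2) parameter-space control points
    closed: bool = False
    degree: int = 3

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float)
        n = len(self.points)
        need = 3 if self.closed else self.degree + 1
        if n < need:
            raise ValueError(
                f"control polygon needs >= {need} points, got {n}"
            )


def geodesic_midpoint(
    space: Space, uA, uB, n_points: int = 15,
    init_path: Optional[GeodesicPath] = None,
) -> np.ndarray:
    """Point at half the arc length of the BVP geodesic from uA to uB."""
    uA = np.asarray(uA, dtype=float)
    uB = np.asarray(uB, dtype=float)
    if np.allclose(uA, uB):
        return uA.copy()
    try:
        path = geodesic_bvp_residual(
            space, uA, uB, n_points=n_points, init_path=init_path
        )
    except ConvergenceError as e:
        raise ConvergenceError(
            f"midpoint BVP failed between {tuple(uA)} and {tuple(uB)}: {e}",
            best_mismatch=e.best_mismatch,
        ) from e
    half = 0.5 * path.s[-1]
    p = np.array(
        [np.interp(half, path.s, path.u[:, k]) for k in range(2)]
    )
    return p


def _midpoints(space, pts, closed):
    pairs = zip(pts, np.roll(pts, -1, axis=0)) if closed else zip(pts[:-1], pts[1:])
    return np.array([geodesic_midpoint(space, a, b) for a, b in pairs])


def subdivide(
    space: Space,
    polygon: ControlPolygon,
    degree: Optional[int] = None,
    n_steps: int = 1,
) -> ControlPolygon:
    """Refine a control polygon by geodesic Lane–Riesenfeld subdivision.

    Each step doubles the vertex count of a closed polygon (duplication =
    insert all edge geodesic midpoints) and then applies ``degree − 1``
    midpoint-averaging rounds.  Degree 1 is pure midpoint insertion: the
    polygon converges onto the piecewise-geodesic polygon itself.
    """
    degree = polygon.degree if degree is None else int(degree)
    if degree < 1:
        raise ValueError("degree must be >= 1")
    pts = polygon.points.copy()
    closed = polygon.closed
    for _ in range(n_steps):
        mids = _midpoints(space, pts, closed)
        if closed:
            refined = np.empty((2 * len(pts), 2))
            refined[0::2] = pts
            refined[1::2] = mids
        else:
            refined = np.empty((2 * len(pts) - 1, 2))
            refined[0::2] = pts
            refined[1::2] = mids
        for _round in range(degree - 1):
            averaged = _midpoints(space, refined, closed)
            if closed:
                refined = averaged
            else:
                refined = np.vstack([pts[0], averaged[1:-1], pts[-1]]) \
                    if len(averaged) > 2 else averaged
        pts = refined
    return ControlPolygon(pts, closed=closed, degree=degree)
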