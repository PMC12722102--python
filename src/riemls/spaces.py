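"""2-D Riemannian spaces: embedded parametric surfaces and abstract metrics.

A :class:`Space` exposes the metric tensor ``g_ij``, its inverse, Christoffel
symbols ``Γ^k_ij``, and Gaussian curvature at any parameter point ``u=(p,q)``.
Embedded surfaces additionally expose the immersion ``S(u)``, the covariant
basis ``S_p, S_q``, the unit normal, the second fundamental form, and
principal/mean curvatures, and compute Christoffel symbols by projecting the
second partials onto the contravariant basis:

    Γ^k_ij = g^{kl} (∂_i ∂_j S · S_l)

Abstract spaces derive everything intrinsically from the metric alone via the
Levi-Civita connection,

    Γ^k_ij = ½ g^{kl} (∂_i g_{jl} + ∂_j g_{il} − ∂_l g_{ij}),

and the Brioschi formula for Gaussian curvature.  For embedded surfaces both
routes agree — curvature and connection are intrinsic — which the test suite
uses as a cross-check.

Coordinate conventions: the sphere uses colatitude θ ∈ (0, π) and periodic
azimuth φ ∈ [0, 2π); both torus angles are periodic; angles are radians
internally.  Evaluation within ``degenerate_eps`` of a degenerate locus (a
sphere pole, the pseudosphere rim) raises :class:`DegeneratePointError`
unless clamped evaluation is requested, in which case the coordinate is
nudged to the locus ± eps.
"""

from __future__ import annotations

import math
from typing import Callable, Optional, Sequence, Tuple

import numpy as np

from .errors import DegeneratePointError, MetricError, SpaceError

__all__ = [
    "Space",
    "ParametricSurface",
    "MetricSpace2D",
    "Plane",
    "Sphere",
    "Ellipsoid",
    "Torus",
    "SurfaceOfRevolution",
    "Pseudosphere",
    "Pin",
    "EggBox",
    "BSplinePatch",
    "PoincareHalfPlane",
    "make_surface",
    "make_metric_space",
    "conformal_metric_space",
    "distance_metric_space",
    "christoffel",
    "gaussian_curvature",
    "surface_frame",
    "validate_space",
]

_INF = float("inf")


class Space:
    """Abstract base for 2-D Riemannian spaces."""

    dim = 2
    is_embedded = False
    #: ((p_min, p_max), (q_min, q_max)); infinities allowed on open axes.
    bounds: Tuple[Tuple[float, float], Tuple[float, float]] = (
        (-_INF, _INF),
        (-_INF, _INF),
    )
    #: per-axis periodicity flags
    periodic: Tuple[bool, bool] = (False, False)
    #: (axis, value) loci where the chart degenerates (metric singular)
    degenerate_loci: Sequence[Tuple[int, float]] = ()
    degenerate_eps = 1e-8

    # -- metric ------------------------------------------------------------
    def metric(self, u) -> np.ndarray:
        raise NotImplementedError

    def inverse_metric(self, u) -> np.ndarray:
        g = self.metric(u)
        det = g[0, 0] * g[1, 1] - g[0, 1] * g[1, 0]
        if abs(det) < 1e-300:
            raise DegeneratePointError(f"singular metric at u={u}")
        return np.array(
            [[g[1, 1], -g[0, 1]], [-g[1, 0], g[0, 0]]]
        ) / det

    def metric_derivs(self, u) -> np.ndarray:
        """∂_l g_ij, indexed [l, i, j]; central finite differences."""
        u = np.asarray(u, dtype=float)
        out = np.empty((2, 2, 2))
        for l in range(2):
            h = self._fd_step(l)
            up, um = u.copy(), u.copy()
            up[l] += h
            um[l] -= h
            out[l] = (self.metric(up) - self.metric(um)) / (2 * h)
        return out

    def _fd_step(self, axis: int) -> float:
        lo, hi = self.bounds[axis]
        extent = hi - lo if math.isfinite(hi - lo) else 1.0
        return 1e-5 * max(1.0, extent)

    # -- connection and curvature -------------------------------------------
    def christoffel(self, u, clamp: bool = False) -> np.ndarray:
        """Γ^k_ij indexed [k, i, j] (symmetric in i, j)."""
        u = self._guard(u, clamp)
        return self.christoffel_intrinsic(u)

    def christoffel_intrinsic(self, u) -> np.ndarray:
        dg = self.metric_derivs(u)
        ginv = self.inverse_metric(u)
        # Γ^k_ij = ½ g^{kl} (∂_i g_jl + ∂_j g_il − ∂_l g_ij)
        # lower-index symbols Γ_lij (unrolled: hot path of the integrator)
        d0, d1 = dg[0], dg[1]
        low = np.empty((2, 2, 2))
        for l in range(2):
            low[l, 0, 0] = d0[0, l] + d0[0, l] - dg[l, 0, 0]
            low[l, 0, 1] = d0[1, l] + d1[0, l] - dg[l, 0, 1]
            low[l, 1, 0] = low[l, 0, 1]
            low[l, 1, 1] = d1[1, l] + d1[1, l] - dg[l, 1, 1]
        gamma = np.empty((2, 2, 2))
        for k in range(2):
            gamma[k] = 0.5 * (ginv[k, 0] * low[0] + ginv[k, 1] * low[1])
        return gamma

    def gaussian_curvature(self, u, clamp: bool = False) -> float:
        u = self._guard(u, clamp)
        return self._curvature_intrinsic(u)

    def _curvature_intrinsic(self, u) -> float:
        """Brioschi formula with finite-difference metric derivatives."""
        u = np.asarray(u, dtype=float)
        hp, hq = self._fd_step(0), self._fd_step(1)

        def comp(v):
            g = self.metric(v)
            return g[0, 0], g[0, 1], g[1, 1]

        E, F, G = comp(u)
        Ep = np.array(comp(u + [hp, 0]))
        Em = np.array(comp(u - [hp, 0]))
        Eq = np.array(comp(u + [0, hq]))
        Eq_m = np.array(comp(u - [0, hq]))
        d_p = (Ep - Em) / (2 * hp)  # (E_u, F_u, G_u)
        d_q = (Eq - Eq_m) / (2 * hq)
        E_u, F_u, G_u = d_p
        E_v, F_v, G_v = d_q
        c0 = np.array([E, F, G])
        E_vv = ((Eq + Eq_m - 2 * c0) / hq**2)[0]
        G_uu = ((Ep + Em - 2 * c0) / hp**2)[2]
        Fpp = comp(u + [hp, hq])[1]
        Fpm = comp(u + [hp, -hq])[1]
        Fmp = comp(u + [-hp, hq])[1]
        Fmm = comp(u + [-hp, -hq])[1]
        F_uv = (Fpp - Fpm - Fmp + Fmm) / (4 * hp * hq)

        M1 = np.array(
            [
                [-0.5 * E_vv + F_uv - 0.5 * G_uu, 0.5 * E_u, F_u - 0.5 * E_v],
                [F_v - 0.5 * G_u, E, F],
                [0.5 * G_v, F, G],
            ]
        )
        M2 = np.array(
            [[0.0, 0.5 * E_v, 0.5 * G_u], [0.5 * E_v, E, F], [0.5 * G_u, F, G]]
        )
        det_g = E * G - F * F
        return float((np.linalg.det(M1) - np.linalg.det(M2)) / det_g**2)

    # -- tangent-space algebra ----------------------------------------------
    def inner(self, u, X, Y) -> float:
        g = self.metric(u)
        return float(np.asarray(X) @ g @ np.asarray(Y))

    def norm(self, u, X) -> float:
        return math.sqrt(max(self.inner(u, X, X), 0.0))

    def orthonormal_basis(self, u) -> np.ndarray:
        """Gram–Schmidt basis of the tangent plane from the coordinate basis.

        Returns a 2×2 matrix ``B`` whose columns are the components of the
        orthonormal vectors (E1, E2) in coordinate basis; positively oriented
        with respect to (e_p, e_q).
        """
        g = self.metric(u)
        g11 = g[0, 0]
        if g11 <= 0:
            raise DegeneratePointError(f"metric not positive at u={u}")
        e1 = np.array([1.0 / math.sqrt(g11), 0.0])
        w = np.array([-g[0, 1] / g11, 1.0])
        n2 = g[1, 1] - g[0, 1] ** 2 / g11
        if n2 <= 0:
            raise DegeneratePointError(f"rank-deficient basis at u={u}")
        e2 = w / math.sqrt(n2)
        return np.column_stack([e1, e2])

    # -- domain handling -----------------------------------------------------
    def wrap(self, u) -> np.ndarray:
        """Wrap periodic axes into their fundamental interval."""
        u = np.array(u, dtype=float)
        for a in range(2):
            if self.periodic[a]:
                lo, hi = self.bounds[a]
                u[a] = lo + (u[a] - lo) % (hi - lo)
        return u

    def contains(self, u, tol: float = 0.0) -> bool:
        for a in range(2):
            if self.periodic[a]:
                continue
            lo, hi = self.bounds[a]
            if u[a] < lo - tol or u[a] > hi + tol:
                return False
        return True

    def _guard(self, u, clamp: bool) -> np.ndarray:
        u = self.wrap(u)
        eps = self.degenerate_eps
        for axis, value in self.degenerate_loci:
            d = u[axis] - value
            if abs(d) < eps:
                if not clamp:
                    raise DegeneratePointError(
                        f"u={tuple(u)} within {eps} of degenerate locus "
                        f"axis {axis} = {value}"
                    )
                u[axis] = value + math.copysign(eps, d if d != 0 else 1.0)
        return u

    def clamp_into_domain(self, u) -> np.ndarray:
        u = self.wrap(u)
        eps = self.degenerate_eps
        for a in range(2):
            if not self.periodic[a]:
                lo, hi = self.bounds[a]
                u[a] = min(max(u[a], lo + eps if math.isfinite(lo) else u[a]),
                           hi - eps if math.isfinite(hi) else u[a])
        return self._guard(u, clamp=True)


# ---------------------------------------------------------------------------
# Embedded parametric surfaces


class ParametricSurface(Space):
    """A regular immersion ``S(p, q) → R³`` with metric ``g_ij = S_i · S_j``."""

    is_embedded = True

    def point(self, u) -> np.ndarray:
        raise NotImplementedError

    def partials(self, u) -> Tuple[np.ndarray, np.ndarray]:
        """(S_p, S_q); finite differences unless overridden analytically."""
        u = np.asarray(u, dtype=float)
        hp, hq = self._fd_step(0), self._fd_step(1)
        sp = (self.point(u + [hp, 0]) - self.point(u - [hp, 0])) / (2 * hp)
        sq = (self.point(u + [0, hq]) - self.point(u - [0, hq])) / (2 * hq)
        return sp, sq

    def second_partials(self, u):
        """(S_pp, S_pq, S_qq); finite differences unless overridden."""
        u = np.asarray(u, dtype=float)
        hp, hq = self._fd_step(0), self._fd_step(1)
        s0 = self.point(u)
        spp = (self.point(u + [hp, 0]) + self.point(u - [hp, 0]) - 2 * s0) / hp**2
        sqq = (self.point(u + [0, hq]) + self.point(u - [0, hq]) - 2 * s0) / hq**2
        spq = (
            self.point(u + [hp, hq])
            - self.point(u + [hp, -hq])
            - self.point(u + [-hp, hq])
            + self.point(u + [-hp, -hq])
        ) / (4 * hp * hq)
        return spp, spq, sqq

    def metric(self, u) -> np.ndarray:
        sp, sq = self.partials(u)
        return np.array(
            [[sp @ sp, sp @ sq], [sq @ sp, sq @ sq]]
        )

    def jacobian(self, u) -> np.ndarray:
        """Pushforward operator: 3×2 matrix with columns S_p, S_q."""
        sp, sq = self.partials(u)
        return np.column_stack([sp, sq])

    def pushforward(self, u, X) -> np.ndarray:
        sp, sq = self.partials(u)
        return X[0] * sp + X[1] * sq

    def normal(self, u) -> np.ndarray:
        sp, sq = self.partials(u)
        n = np.cross(sp, sq)
        ln = np.linalg.norm(n)
        if ln < 1e-14:
            raise DegeneratePointError(f"immersion not regular at u={u}")
        return n / ln

    def second_fundamental_form(self, u) -> np.ndarray:
        n = self.normal(u)
        spp, spq, sqq = self.second_partials(u)
        return np.array([[spp @ n, spq @ n], [spq @ n, sqq @ n]])

    def shape_operator(self, u) -> np.ndarray:
        return self.inverse_metric(u) @ self.second_fundamental_form(u)

    def principal_curvatures(self, u):
        """(κ1, κ2, dir1, dir2): eigen-decomposition of the shape operator.

        κ1 ≥ κ2; directions are parameter-space eigenvectors, unit metric
        norm; sign positive when the surface bends toward +n.
        """
        W = self.shape_operator(u)
        vals, vecs = np.linalg.eig(W)
        vals = np.real(vals)
        vecs = np.real(vecs)
        order = np.argsort(vals)[::-1]
        vals, vecs = vals[order], vecs[:, order]
        dirs = []
        for j in range(2):
            v = vecs[:, j]
            dirs.append(v / max(self.norm(u, v), 1e-300))
        return vals[0], vals[1], dirs[0], dirs[1]

    def mean_curvature(self, u) -> float:
        return float(0.5 * np.trace(self.shape_operator(u)))

    def gaussian_curvature(self, u, clamp: bool = False) -> float:
        u = self._guard(u, clamp)
        II = self.second_fundamental_form(u)
        g = self.metric(u)
        return float(np.linalg.det(II) / np.linalg.det(g))

    def christoffel(self, u, clamp: bool = False) -> np.ndarray:
        """Embedding route: project second partials onto the contravariant basis."""
        u = self._guard(u, clamp)
        sp, sq = self.partials(u)
        spp, spq, sqq = self.second_partials(u)
        g = np.array([[sp @ sp, sp @ sq], [sq @ sp, sq @ sq]])
        det = g[0, 0] * g[1, 1] - g[0, 1] * g[1, 0]
        ginv = np.array([[g[1, 1], -g[0, 1]], [-g[1, 0], g[0, 0]]]) / det
        basis = (sp, sq)
        second = ((spp, spq), (spq, sqq))
        gamma = np.empty((2, 2, 2))
        for k in range(2):
            for i in range(2):
                for j in range(2):
                    s = 0.0
                    for l in range(2):
                        s += ginv[k, l] * (second[i][j] @ basis[l])
                    gamma[k, i, j] = s
        return gamma

    def sample_grid(self, n: int = 32, margin: float = 0.0):
        """(n×n) parameter grid and 3-D points, for export/plot context."""
        (p0, p1), (q0, q1) = self.bounds
        p0, p1 = p0 + margin, p1 - margin
        q0, q1 = q0 + margin, q1 - margin
        ps = np.linspace(p0, p1, n)
        qs = np.linspace(q0, q1, n)
        pts = np.array([[self.point((p, q)) for q in qs] for p in ps])
        return ps, qs, pts

    def export_obj(self, fh, n: int = 32, margin: float = 1e-3):
        """Write a triangulated sampling of the surface as Wavefront OBJ."""
        close = False
        if isinstance(fh, str):
            fh, close = open(fh, "w"), True
        try:
            _, _, pts = self.sample_grid(n=n, margin=margin)
            fh.write("# riemls surface mesh\n")
            for i in range(n):
                for j in range(n):
                    x, y, z = pts[i, j]
                    fh.write(f"v {x:.9g} {y:.9g} {z:.9g}\n")
            for i in range(n - 1):
                for j in range(n - 1):
                    a = i * n + j + 1
                    b, c, d = a + 1, a + n, a + n + 1
                    fh.write(f"f {a} {b} {d}\nf {a} {d} {c}\n")
        finally:
            if close:
                fh.close()


# -- built-in surfaces -------------------------------------------------------


class Plane(ParametricSurface):
    """The Euclidean plane, S(p, q) = (p, q, 0)."""

    def point(self, u):
        return np.array([u[0], u[1], 0.0])

    def partials(self, u):
        return np.array([1.0, 0.0, 0.0]), np.array([0.0, 1.0, 0.0])

    def second_partials(self, u):
        z = np.zeros(3)
        return z, z, z

    def metric(self, u):
        return np.eye(2)

    def christoffel(self, u, clamp=False):
        return np.zeros((2, 2, 2))

    def gaussian_curvature(self, u, clamp=False):
        return 0.0


class Sphere(ParametricSurface):
    """Sphere of radius R; u = (colatitude θ, azimuth φ)."""

    def __init__(self, R: float = 1.0):
        if R <= 0:
            raise SpaceError("sphere radius must be positive")
        self.R = float(R)
        self.bounds = ((0.0, math.pi), (0.0, 2 * math.pi))
        self.periodic = (False, True)
        self.degenerate_loci = ((0, 0.0), (0, math.pi))

    def point(self, u):
        th, ph = u
        R = self.R
        st, ct = math.sin(th), math.cos(th)
        return np.array([R * st * math.cos(ph), R * st * math.sin(ph), R * ct])

    def partials(self, u):
        th, ph = u
        R = self.R
        st, ct = math.sin(th), math.cos(th)
        sp, cp = math.sin(ph), math.cos(ph)
        s_th = np.array([R * ct * cp, R * ct * sp, -R * st])
        s_ph = np.array([-R * st * sp, R * st * cp, 0.0])
        return s_th, s_ph

    def second_partials(self, u):
        th, ph = u
        R = self.R
        st, ct = math.sin(th), math.cos(th)
        sp, cp = math.sin(ph), math.cos(ph)
        s_tt = np.array([-R * st * cp, -R * st * sp, -R * ct])
        s_tp = np.array([-R * ct * sp, R * ct * cp, 0.0])
        s_pp = np.array([-R * st * cp, -R * st * sp, 0.0])
        return s_tt, s_tp, s_pp

    def metric(self, u):
        st = math.sin(u[0])
        return np.array([[self.R**2, 0.0], [0.0, self.R**2 * st * st]])


class Ellipsoid(ParametricSurface):
    """Ellipsoid with semi-axes (a, b, c); spherical-style coordinates."""

    def __init__(self, a: float, b: float, c: float):
        if min(a, b, c) <= 0:
            raise SpaceError("ellipsoid semi-axes must be positive")
        self.a, self.b, self.c = float(a), float(b), float(c)
        self.bounds = ((0.0, math.pi), (0.0, 2 * math.pi))
        self.periodic = (False, True)
        self.degenerate_loci = ((0, 0.0), (0, math.pi))

    def point(self, u):
        th, ph = u
        st, ct = math.sin(th), math.cos(th)
        return np.array(
            [self.a * st * math.cos(ph), self.b * st * math.sin(ph), self.c * ct]
        )

    def partials(self, u):
        th, ph = u
        st, ct = math.sin(th), math.cos(th)
        sp, cp = math.sin(ph), math.cos(ph)
        s_th = np.array([self.a * ct * cp, self.b * ct * sp, -self.c * st])
        s_ph = np.array([-self.a * st * sp, self.b * st * cp, 0.0])
        return s_th, s_ph

    def second_partials(self, u):
        th, ph = u
        st, ct = math.sin(th), math.cos(th)
        sp, cp = math.sin(ph), math.cos(ph)
        s_tt = np.array([-self.a * st * cp, -self.b * st * sp, -self.c * ct])
        s_tp = np.array([-self.a * ct * sp, self.b * ct * cp, 0.0])
        s_pp = np.array([-self.a * st * cp, -self.b * st * sp, 0.0])
        return s_tt, s_tp, s_pp

    @property
    def is_revolution(self) -> bool:
        return abs(self.a - self.b) < 1e-12

    def revolution_radius(self, u) -> float:
        """Distance to the revolution axis (a = b case)."""
        return self.a * math.sin(u[0])


class Torus(ParametricSurface):
    """Torus: u = (major angle, minor angle), both periodic; requires r < R."""

    def __init__(self, R: float = 1.0, r: float = 0.3):
        if not (0 < r < R):
            raise SpaceError("torus requires 0 < r < R")
        self.R, self.r = float(R), float(r)
        self.bounds = ((0.0, 2 * math.pi), (0.0, 2 * math.pi))
        self.periodic = (True, True)

    def point(self, u):
        a, b = u
        w = self.R + self.r * math.cos(b)
        return np.array([w * math.cos(a), w * math.sin(a), self.r * math.sin(b)])

    def partials(self, u):
        a, b = u
        ca, sa = math.cos(a), math.sin(a)
        cb, sb = math.cos(b), math.sin(b)
        w = self.R + self.r * cb
        s_a = np.array([-w * sa, w * ca, 0.0])
        s_b = np.array([-self.r * sb * ca, -self.r * sb * sa, self.r * cb])
        return s_a, s_b

    def second_partials(self, u):
        a, b = u
        ca, sa = math.cos(a), math.sin(a)
        cb, sb = math.cos(b), math.sin(b)
        w = self.R + self.r * cb
        s_aa = np.array([-w * ca, -w * sa, 0.0])
        s_ab = np.array([self.r * sb * sa, -self.r * sb * ca, 0.0])
        s_bb = np.array(
            [-self.r * cb * ca, -self.r * cb * sa, -self.r * sb]
        )
        return s_aa, s_ab, s_bb

    def metric(self, u):
        w = self.R + self.r * math.cos(u[1])
        return np.array([[w * w, 0.0], [0.0, self.r**2]])


class SurfaceOfRevolution(ParametricSurface):
    """Profile (r(t), z(t)) revolved about the z axis; u = (t, azimuth φ).

    Analytic profile derivatives may be supplied; otherwise they are taken by
    central differences on the profile functions.
    """

    def __init__(
        self,
        r: Callable[[float], float],
        z: Callable[[float], float],
        t_range: Tuple[float, float],
        dr: Optional[Callable] = None,
        dz: Optional[Callable] = None,
        d2r: Optional[Callable] = None,
        d2z: Optional[Callable] = None,
    ):
        self.r_fn, self.z_fn = r, z
        self.bounds = (tuple(map(float, t_range)), (0.0, 2 * math.pi))
        self.periodic = (False, True)
        h = 1e-6 * max(1.0, self.bounds[0][1] - self.bounds[0][0])
        self.dr = dr or (lambda t: (r(t + h) - r(t - h)) / (2 * h))
        self.dz = dz or (lambda t: (z(t + h) - z(t - h)) / (2 * h))
        self.d2r = d2r or (lambda t: (r(t + h) - 2 * r(t) + r(t - h)) / h**2)
        self.d2z = d2z or (lambda t: (z(t + h) - 2 * z(t) + z(t - h)) / h**2)

    def point(self, u):
        t, ph = u
        rr = self.r_fn(t)
        return np.array([rr * math.cos(ph), rr * math.sin(ph), self.z_fn(t)])

    def partials(self, u):
        t, ph = u
        rr, dr, dz = self.r_fn(t), self.dr(t), self.dz(t)
        cp, sp = math.cos(ph), math.sin(ph)
        s_t = np.array([dr * cp, dr * sp, dz])
        s_p = np.array([-rr * sp, rr * cp, 0.0])
        return s_t, s_p

    def second_partials(self, u):
        t, ph = u
        rr, dr = self.r_fn(t), self.dr(t)
        d2r, d2z = self.d2r(t), self.d2z(t)
        cp, sp = math.cos(ph), math.sin(ph)
        s_tt = np.array([d2r * cp, d2r * sp, d2z])
        s_tp = np.array([-dr * sp, dr * cp, 0.0])
        s_pp = np.array([-rr * cp, -rr * sp, 0.0])
        return s_tt, s_tp, s_pp

    def revolution_radius(self, u) -> float:
        return float(self.r_fn(u[0]))


class Pseudosphere(SurfaceOfRevolution):
    """Tractrix of revolution (tractroid): constant curvature K = −1/R².

    Profile r(t) = R sech t, z(t) = R (t − tanh t), t > 0.  The rim t = 0 is
    a degenerate locus of the chart.
    """

    def __init__(self, R: float = 1.0, t_range: Tuple[float, float] = (0.05, 3.0)):
        if R <= 0:
            raise SpaceError("pseudosphere radius must be positive")
        self.R = float(R)
        sech = lambda t: 1.0 / math.cosh(t)
        super().__init__(
            r=lambda t: R * sech(t),
            z=lambda t: R * (t - math.tanh(t)),
            t_range=t_range,
            dr=lambda t: -R * sech(t) * math.tanh(t),
            dz=lambda t: R * math.tanh(t) ** 2,
            d2r=lambda t: R * sech(t) * (math.tanh(t) ** 2 - sech(t) ** 2),
            d2z=lambda t: 2 * R * math.tanh(t) * sech(t) ** 2,
        )
        self.degenerate_loci = ((0, 0.0),)


class Pin(SurfaceOfRevolution):
    """A funnel narrowing from a wide base to a thin neck (papilla-like).

    Profile r(t) = r_neck + (r_base − r_neck)(1 − tanh(k t))/2 with z = t,
    t ∈ [−T, T]: radius ≈ r_base for t ≪ 0, ≈ r_neck for t ≫ 0.  Geodesics
    climbing the pin obey the Clairaut bound: those whose invariant exceeds
    r_neck turn back before the neck and coil.
    """

    def __init__(
        self,
        r_base: float = 1.0,
        r_neck: float = 0.2,
        k: float = 2.0,
        T: float = 3.0,
    ):
        if not (0 < r_neck < r_base):
            raise SpaceError("pin requires 0 < r_neck < r_base")
        self.r_base, self.r_neck, self.k = float(r_base), float(r_neck), float(k)
        amp = 0.5 * (r_base - r_neck)
        sech2 = lambda x: 1.0 / math.cosh(x) ** 2
        super().__init__(
            r=lambda t: r_neck + amp * (1 - math.tanh(k * t)),
            z=lambda t: t,
            t_range=(-T, T),
            dr=lambda t: -amp * k * sech2(k * t),
            dz=lambda t: 1.0,
            d2r=lambda t: 2 * amp * k * k * sech2(k * t) * math.tanh(k * t),
            d2z=lambda t: 0.0,
        )


class EggBox(ParametricSurface):
    """Sinusoidal bump field z = A sin(p) sin(q): alternating K > 0 domes."""

    def __init__(self, A: float = 0.5, extent: float = 4 * math.pi):
        self.A = float(A)
        self.bounds = ((-extent, extent), (-extent, extent))

    def point(self, u):
        p, q = u
        return np.array([p, q, self.A * math.sin(p) * math.sin(q)])

    def partials(self, u):
        p, q = u
        A = self.A
        s_p = np.array([1.0, 0.0, A * math.cos(p) * math.sin(q)])
        s_q = np.array([0.0, 1.0, A * math.sin(p) * math.cos(q)])
        return s_p, s_q

    def second_partials(self, u):
        p, q = u
        A = self.A
        s_pp = np.array([0.0, 0.0, -A * math.sin(p) * math.sin(q)])
        s_pq = np.array([0.0, 0.0, A * math.cos(p) * math.cos(q)])
        s_qq = np.array([0.0, 0.0, -A * math.sin(p) * math.sin(q)])
        return s_pp, s_pq, s_qq


class BSplinePatch(ParametricSurface):
    """Clamped tensor-product B-spline patch over [0,1]²; control grid mutable.

    Polynomial (non-rational) patch; degree per axis.  Point and partial
    evaluation go through per-axis B-spline basis functions; second partials
    via finite differences.
    """

    def __init__(self, control: np.ndarray, degree: Tuple[int, int] = (3, 3)):
        control = np.asarray(control, dtype=float)
        if control.ndim != 3 or control.shape[2] != 3:
            raise SpaceError("control grid must have shape (m, n, 3)")
        m, n, _ = control.shape
        ku, kv = degree
        if m < ku + 1 or n < kv + 1:
            raise SpaceError("control grid too small for requested degree")
        self.control = control
        self.degree = (ku, kv)
        self.bounds = ((0.0, 1.0), (0.0, 1.0))
        self._tu = self._clamped_knots(m, ku)
        self._tv = self._clamped_knots(n, kv)

    @staticmethod
    def _clamped_knots(n_ctrl, k):
        n_int = n_ctrl - k + 1
        return np.concatenate(
            [np.zeros(k), np.linspace(0, 1, n_int), np.ones(k)]
        )

    def _basis(self, t, knots, k, n_ctrl, der=0):
        from scipy.interpolate import BSpline

        t = min(max(float(t), 0.0), 1.0 - 1e-12)
        b = np.empty(n_ctrl)
        for i in range(n_ctrl):
            c = np.zeros(n_ctrl)
            c[i] = 1.0
            spl = BSpline(knots, c, k)
            b[i] = spl(t, nu=der)
        return b

    def point(self, u):
        m, n, _ = self.control.shape
        bu = self._basis(u[0], self._tu, self.degree[0], m)
        bv = self._basis(u[1], self._tv, self.degree[1], n)
        return np.einsum("i,j,ijk->k", bu, bv, self.control)

    def partials(self, u):
        m, n, _ = self.control.shape
        bu = self._basis(u[0], self._tu, self.degree[0], m)
        bv = self._basis(u[1], self._tv, self.degree[1], n)
        du = self._basis(u[0], self._tu, self.degree[0], m, der=1)
        dv = self._basis(u[1], self._tv, self.degree[1], n, der=1)
        s_p = np.einsum("i,j,ijk->k", du, bv, self.control)
        s_q = np.einsum("i,j,ijk->k", bu, dv, self.control)
        return s_p, s_q


# ---------------------------------------------------------------------------
# Abstract metric spaces


class MetricSpace2D(Space):
    """An abstract 2-D Riemannian space given by metric component functions.

    ``g11``, ``g12``, ``g22`` are callables of ``(p, q)``.  All geometry is
    intrinsic: Christoffel symbols come from the metric derivatives
    (analytic when ``dg`` is supplied, else finite differences) and Gaussian
    curvature from the Brioschi formula.
    """

    def __init__(
        self,
        g11: Callable,
        g12: Callable,
        g22: Callable,
        bounds=((-_INF, _INF), (-_INF, _INF)),
        periodic=(False, False),
        dg: Optional[Callable] = None,
        name: str = "metric2d",
    ):
        self._g11, self._g12, self._g22 = g11, g12, g22
        self.bounds = tuple(tuple(map(float, b)) for b in bounds)
        self.periodic = tuple(periodic)
        self._dg = dg
        self.name = name

    def metric(self, u):
        p, q = float(u[0]), float(u[1])
        g11 = self._g11(p, q)
        g12 = self._g12(p, q)
        g22 = self._g22(p, q)
        return np.array([[g11, g12], [g12, g22]])

    def metric_derivs(self, u):
        if self._dg is not None:
            return np.asarray(self._dg(float(u[0]), float(u[1])), dtype=float)
        return super().metric_derivs(u)


class PoincareHalfPlane(MetricSpace2D):
    """Beltrami–Poincaré half-plane: g_ij = δ_ij / y² on y > 0; K = −1.

    Geodesics are half-circles centred on the x-axis (or vertical lines);
    the distance between two points has the closed form
    arccosh(1 + (Δx² + Δy²) / (2 y₁ y₂)), used as a test oracle.
    """

    def __init__(self, analytic: bool = True):
        def g11(x, y):
            return 1.0 / (y * y)

        def zero(x, y):
            return 0.0

        dg = None
        if analytic:

            def dg(x, y):
                d = np.zeros((2, 2, 2))
                d[1, 0, 0] = -2.0 / y**3
                d[1, 1, 1] = -2.0 / y**3
                return d

        super().__init__(
            g11, zero, g11,
            bounds=((-_INF, _INF), (0.0, _INF)),
            dg=dg,
            name="poincare_half_plane",
        )

    @staticmethod
    def distance_closed_form(a, b) -> float:
        dx = b[0] - a[0]
        dy = b[1] - a[1]
        return math.acosh(1.0 + (dx * dx + dy * dy) / (2.0 * a[1] * b[1]))


def conformal_metric_space(
    factor: Callable[[float, float], float],
    bounds=((-_INF, _INF), (-_INF, _INF)),
    name: str = "conformal",
) -> MetricSpace2D:
    """Isotropic metric g_ij = factor(p, q)² δ_ij."""

    def g11(p, q):
        f = factor(p, q)
        return f * f

    return MetricSpace2D(g11, lambda p, q: 0.0, g11, bounds=bounds, name=name)


def distance_metric_space(
    center=(0.0, 0.0),
    a: float = 0.2,
    b: float = 1.0,
    mode: str = "linear",
    bounds=((-_INF, _INF), (-_INF, _INF)),
) -> MetricSpace2D:
    """Conformal metric sourced by the Euclidean distance d to a centre point.

    ``mode="linear"``: conformal factor a + b·d — small metric near the
    centre, growing with distance (forms near the centre curve strongly).
    ``mode="inverse"``: factor a + b/(1 + d) — metric inversely related to
    the distance; geodesics bend away from the source (shadow avoidance).
    """
    cx, cy = center

    def dist(p, q):
        return math.hypot(p - cx, q - cy)

    if mode == "linear":
        fac = lambda p, q: a + b * dist(p, q)
    elif mode == "inverse":
        fac = lambda p, q: a + b / (1.0 + dist(p, q))
    else:
        raise SpaceError(f"unknown distance-metric mode {mode!r}")
    return conformal_metric_space(fac, bounds=bounds, name=f"distance_{mode}")


# ---------------------------------------------------------------------------
# Factories and module-level wrappers

_SURFACES = {
    "plane": Plane,
    "sphere": Sphere,
    "ellipsoid": Ellipsoid,
    "torus": Torus,
    "pseudosphere": Pseudosphere,
    "revolution": SurfaceOfRevolution,
    "bspline_patch": BSplinePatch,
    "pin": Pin,
    "eggbox": EggBox,
}


def make_surface(kind: str, *args, **kwargs) -> ParametricSurface:
    """Instantiate a built-in surface by name (case-insensitive)."""
    cls = _SURFACES.get(kind.lower())
    if cls is None:
        raise SpaceError(
            f"unknown surface kind {kind!r}; choose from {sorted(_SURFACES)}"
        )
    return cls(*args, **kwargs)


def make_metric_space(
    g11, g12, g22, bounds, periodic=(False, False), validate: bool = True,
    n_grid: int = 8,
) -> MetricSpace2D:
    """Build an abstract space, validating positive-definiteness on a grid."""
    space = MetricSpace2D(g11, g12, g22, bounds=bounds, periodic=periodic)
    if validate:
        validate_space(space, n_grid)
    return space


def validate_space(space: Space, n: int = 8, margin: float = 1e-3):
    """Assert metric symmetry and positive-definiteness on an interior grid."""
    (p0, p1), (q0, q1) = space.bounds
    if not all(map(math.isfinite, (p0, p1, q0, q1))):
        p0 = p0 if math.isfinite(p0) else -2.0
        p1 = p1 if math.isfinite(p1) else 2.0
        q0 = q0 if math.isfinite(q0) else (0.1 if space.bounds[1][0] == 0 else -2.0)
        q1 = q1 if math.isfinite(q1) else 2.0
    dp, dq = (p1 - p0), (q1 - q0)
    for p in np.linspace(p0 + margin * dp, p1 - margin * dp, n):
        for q in np.linspace(q0 + margin * dq, q1 - margin * dq, n):
            try:
                g = space.metric((p, q))
            except DegeneratePointError:
                continue
            if abs(g[0, 1] - g[1, 0]) > 1e-9 * (1 + abs(g[0, 1])):
                raise MetricError(f"metric not symmetric at ({p}, {q})")
            tr, det = g[0, 0] + g[1, 1], np.linalg.det(g)
            if det <= 0 or tr <= 0:
                near_degenerate = any(
                    abs((p, q)[ax] - v) < 1e-3 for ax, v in space.degenerate_loci
                )
                if not near_degenerate:
                    raise MetricError(
                        f"metric not positive definite at ({p}, {q})"
                    )
    return True


def christoffel(space: Space, u, clamp: bool = False) -> np.ndarray:
    """Γ^k_ij at u (indexed [k, i, j])."""
    return space.christoffel(u, clamp=clamp)


def gaussian_curvature(space: Space, u, clamp: bool = False) -> float:
    return space.gaussian_curvature(u, clamp=clamp)


def surface_frame(surface: ParametricSurface, u, X):
    """Orthonormal frame (H, L, U) at u with H along the pushforward of X.

    U is the surface normal and L = U × H completes a right-handed frame
    (H × L = U).  Also returns the 3×2 pushforward Jacobian.
    """
    X = np.asarray(X, dtype=float)
    if np.allclose(X, 0):
        raise SpaceError("zero tangent vector has no direction")
    J = surface.jacobian(u)
    H = J @ X
    nH = np.linalg.norm(H)
    if nH < 1e-14:
        raise DegeneratePointError(f"pushforward degenerate at u={u}")
    H = H / nH
    U = surface.normal(u)
    L = np.cross(U, H)
    return H, L, U, J
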