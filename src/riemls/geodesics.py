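"""Geodesic computation: initial-value integration, two boundary-value
solvers, exponential/logarithmic maps, and geodesic distance.

The geodesic equation in parameter coordinates,

    ü^k = − Γ^k_ij u̇^i u̇^j,

is integrated as four coupled first-order ODEs in the state (p, q, ṗ, q̇)
with a fixed-step classical 4th-order Runge–Kutta scheme, so paths have
deterministic sample counts for the turtle.  Velocities are renormalised to
unit metric norm after each step by default (controls drift; disable to
check convergence order).

Two boundary-value solvers are provided:

* **shooting** — optimise the launch angle ψ (in a Gram–Schmidt orthonormal
  tangent basis) and arc length l to minimise the endpoint mismatch, measured
  in the embedding when available, else in (periodically unwrapped) parameter
  space; bounded least squares with multi-start over 8 launch angles.
* **residual** — collocation with the trapezoidal rule on the affinely
  parameterised geodesic equation over t ∈ [0, 1], endpoint positions
  clamped, solved by damped Newton with an analytic block-sparse Jacobian
  (∂Γ by finite differences); initial guess is linear interpolation in
  parameter space.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy.optimize import least_squares

from .errors import BoundaryError, ConvergenceError
from .spaces import ParametricSurface, Space

__all__ = [
    "GeodesicPath",
    "geodesic_ivp",
    "geodesic_bvp_shoot",
    "geodesic_bvp_residual",
    "geodesic_distance",
    "exp_map",
    "log_map",
]

#: default integrator arc-length step
DS_DEFAULT = 0.01


@dataclass
class GeodesicPath:
    """A discretised geodesic: parameter positions, velocities, arc length."""

    space: Space
    u: np.ndarray  # (n, 2) parameter points (covering-space coordinates)
    v: np.ndarray  # (n, 2) velocities du/ds
    s: np.ndarray  # (n,) cumulative arc length
    method: str = "ivp"
    iterations: int = 0
    residual: float = 0.0

    @property
    def length(self) -> float:
        return float(self.s[-1])

    @property
    def start(self) -> np.ndarray:
        return self.u[0]

    @property
    def end(self) -> np.ndarray:
        return self.u[-1]

    @property
    def end_tangent(self) -> np.ndarray:
        """Unit-metric-norm tangent at the endpoint (parallel transport of
        the launch direction along the path)."""
        v = self.v[-1]
        n = self.space.norm(self.space.wrap(self.u[-1]), v)
        return v / n

    @property
    def start_tangent(self) -> np.ndarray:
        v = self.v[0]
        n = self.space.norm(self.space.wrap(self.u[0]), v)
        return v / n

    def points3d(self) -> np.ndarray:
        if not self.space.is_embedded:
            raise ValueError("abstract space has no embedding")
        return np.array([self.space.point(self.space.wrap(q)) for q in self.u])

    def resample(self, fractions) -> np.ndarray:
        """Cubic-interpolated parameter points at given arc-length fractions."""
        from scipy.interpolate import interp1d

        kind = "cubic" if len(self.s) >= 4 else "linear"
        f = interp1d(self.s, self.u, axis=0, kind=kind)
        return f(np.asarray(fractions) * self.s[-1])

    def to_csv(self, path_or_buf):
        """Write samples as CSV: s, p, q, dp, dq [, x, y, z]."""
        cols = [self.s, self.u[:, 0], self.u[:, 1], self.v[:, 0], self.v[:, 1]]
        header = "s,p,q,dp,dq"
        if self.space.is_embedded:
            xyz = self.points3d()
            cols += [xyz[:, 0], xyz[:, 1], xyz[:, 2]]
            header += ",x,y,z"
        data = np.column_stack(cols)
        np.savetxt(path_or_buf, data, delimiter=",", header=header, comments="")


def _accel(space: Space, u, v) -> np.ndarray:
    gamma = space.christoffel(u, clamp=True)
    v0, v1 = v
    a = v0 * v0
    b = 2.0 * v0 * v1
    c = v1 * v1
    return np.array(
        [
            -(gamma[0, 0, 0] * a + gamma[0, 0, 1] * b + gamma[0, 1, 1] * c),
            -(gamma[1, 0, 0] * a + gamma[1, 0, 1] * b + gamma[1, 1, 1] * c),
        ]
    )


def _rhs(space, y):
    u, v = y[:2], y[2:]
    return np.concatenate([v, _accel(space, u, v)])


def geodesic_ivp(
    space: Space,
    u0,
    d0,
    length: float,
    n_steps: Optional[int] = None,
    ds: float = DS_DEFAULT,
    renormalize: bool = True,
) -> GeodesicPath:
    """Integrate the geodesic from ``u0`` in direction ``d0`` for ``length``.

    ``d0`` is normalised to unit metric speed, so the curve is arc-length
    parameterised.  Exiting a non-periodic domain raises
    :class:`BoundaryError` carrying the last valid sample.
    """
    u0 = np.asarray(u0, dtype=float)
    d0 = np.asarray(d0, dtype=float)
    if length <= 0:
        raise ValueError("length must be positive")
    n0 = space.norm(space.wrap(u0), d0)
    if n0 < 1e-14:
        raise ValueError("zero initial direction")
    if n_steps is None:
        n_steps = max(10, int(math.ceil(length / ds)))
    h = length / n_steps
    y = np.concatenate([u0, d0 / n0])
    us = np.empty((n_steps + 1, 2))
    vs = np.empty((n_steps + 1, 2))
    us[0], vs[0] = y[:2], y[2:]
    for i in range(n_steps):
        k1 = _rhs(space, y)
        k2 = _rhs(space, y + 0.5 * h * k1)
        k3 = _rhs(space, y + 0.5 * h * k2)
        k4 = _rhs(space, y + h * k3)
        y = y + (h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        # tolerate overshoot up to ~2 steps (chart-degenerate ends such as
        # the sphere pole are reached to float noise beyond the bound)
        if not space.contains(space.wrap(y[:2]), tol=2.0 * h):
            err = BoundaryError(
                f"geodesic left the domain at step {i + 1}",
                last_valid=(us[i].copy(), vs[i].copy()),
            )
            err.partial = GeodesicPath(
                space, us[: i + 1].copy(), vs[: i + 1].copy(),
                np.linspace(0.0, i * h, i + 1), method="ivp",
            )
            raise err
        if renormalize:
            nv = space.norm(space.clamp_into_domain(y[:2]), y[2:])
            if nv > 0:
                y[2:] /= nv
        us[i + 1], vs[i + 1] = y[:2], y[2:]
    s = np.linspace(0.0, length, n_steps + 1)
    return GeodesicPath(space, us, vs, s, method="ivp")


# ---------------------------------------------------------------------------
# Boundary-value solvers


def _lift_near(space: Space, u0, u1) -> np.ndarray:
    """Representative of u1 in the covering space nearest to u0."""
    u0 = np.asarray(u0, dtype=float)
    u1 = np.array(u1, dtype=float)
    for a in range(2):
        if space.periodic[a]:
            lo, hi = space.bounds[a]
            period = hi - lo
            u1[a] = u0[a] + ((u1[a] - u0[a] + period / 2) % period) - period / 2
    return u1


def _mismatch(space: Space, u_end, u1_lifted) -> np.ndarray:
    if space.is_embedded:
        return space.point(space.wrap(u_end)) - space.point(space.wrap(u1_lifted))
    return np.asarray(u_end, dtype=float) - u1_lifted


def geodesic_bvp_shoot(
    space: Space,
    u0,
    u1,
    init_guess: Optional[Tuple[float, float]] = None,
    ds: float = DS_DEFAULT,
    tol: float = 1e-8,
    l_max: Optional[float] = None,
    n_starts: int = 8,
) -> GeodesicPath:
    """Shooting BVP: minimise endpoint mismatch over (launch angle, length).

    The direction is e(ψ) = cos ψ E1 + sin ψ E2 in the Gram–Schmidt
    orthonormal tangent basis at ``u0``.  Mismatch below √tol accepts;
    failing starts are retried from ``n_starts`` evenly spaced angles.
    """
    u0 = np.asarray(u0, dtype=float)
    u1 = _lift_near(space, u0, u1)
    B = space.orthonormal_basis(space.wrap(u0))
    du = u1 - u0
    g = space.metric(space.wrap(u0))
    l0 = math.sqrt(max(du @ g @ du, 1e-12))
    if l_max is None:
        l_max = 4.0 * max(l0, 1.0)

    if init_guess is None:
        comp = np.linalg.solve(B, du)
        psi0 = math.atan2(comp[1], comp[0])
    else:
        psi0, l0 = init_guess

    def run(params):
        psi, l = params
        d = B @ np.array([math.cos(psi), math.sin(psi)])
        return geodesic_ivp(space, u0, d, max(l, 1e-9), ds=ds)

    def make_res(param_space):
        def res(params):
            try:
                path = run(params)
            except BoundaryError as e:
                # strong penalty proportional to the remaining length
                last = e.last_valid[0] if e.last_valid is not None else u0
                base = (last - u1) if param_space else _mismatch(space, last, u1)
                return np.asarray(base) * 10.0
            if param_space:
                return path.u[-1] - u1  # lifted covering-space coordinates
            return _mismatch(space, path.u[-1], u1)

        return res

    def solve(res):
        starts = [(psi0, l0)] + [
            (psi0 + 2 * math.pi * k / n_starts, l0) for k in range(1, n_starts)
        ]
        best = None
        for psi_s, l_s in starts:
            sol = least_squares(
                res,
                x0=[psi_s, max(min(l_s, l_max), 1e-6)],
                bounds=([psi_s - math.pi, 1e-9], [psi_s + math.pi, l_max]),
                xtol=1e-14,
                ftol=1e-14,
                gtol=1e-14,
            )
            cost = 2 * sol.cost  # squared mismatch norm
            if best is None or cost < best[0]:
                best = (cost, sol.x)
            if cost < tol:
                break
        return best

    def wrong_winding(path):
        return any(
            space.periodic[a]
            and abs(path.u[-1][a] - u1[a])
            > 0.5 * (space.bounds[a][1] - space.bounds[a][0])
            for a in range(2)
        )

    cost, x = solve(make_res(param_space=not space.is_embedded))
    path = run(x) if cost < tol else None
    if path is not None and wrong_winding(path):
        # the embedding mismatch accepts any periodic representative of the
        # target; re-solve against the lifted coordinates to pin the winding
        cost2, x2 = solve(make_res(param_space=True))
        if cost2 < tol:
            cost, x, path = cost2, x2, run(x2)
    if path is None or cost >= tol:
        raise ConvergenceError(
            f"shooting failed: best squared mismatch {cost:.3e} >= {tol}",
            best_mismatch=math.sqrt(cost),
        )
    path.method = "shoot"
    path.residual = math.sqrt(cost)
    return path


def geodesic_bvp_residual(
    space: Space,
    u0,
    u1,
    n_points: int = 41,
    tol: float = 1e-8,
    step_tol: float = 1e-10,
    max_iter: int = 50,
    init_path: Optional[GeodesicPath] = None,
) -> GeodesicPath:
    """Collocation BVP: trapezoidal residuals solved by damped Newton.

    The geodesic equation is discretised on t ∈ [0, 1] with constant affine
    speed; residuals r_i = y_{i+1} − y_i − (Δt/2)(f(y_{i+1}) + f(y_i)) with
    the endpoint positions clamped.  Converged when max |r| < ``tol`` or the
    Newton step falls below ``step_tol``.
    """
    if n_points < 3:
        raise ValueError("n_points must be >= 3")
    u0 = np.asarray(u0, dtype=float)
    u1 = _lift_near(space, u0, u1)
    n = n_points
    dt = 1.0 / (n - 1)

    if init_path is not None:
        frac = np.linspace(0, 1, n)
        U = init_path.resample(frac)
        V = np.gradient(U, dt, axis=0)
    else:
        ts = np.linspace(0, 1, n)[:, None]
        U = u0 + ts * (u1 - u0)
        V = np.tile(u1 - u0, (n, 1))
    Y = np.concatenate([U, V], axis=1)  # (n, 4)

    def f_of(y):
        return np.concatenate([y[2:], _accel(space, y[:2], y[2:])])

    def residuals(Y):
        F = np.array([f_of(y) for y in Y])
        r = Y[1:] - Y[:-1] - 0.5 * dt * (F[1:] + F[:-1])  # (n-1, 4)
        cons = np.concatenate([Y[0, :2] - u0, Y[-1, :2] - u1])
        return np.concatenate([r.ravel(), cons])

    def jac_f(y):
        """4×4 Jacobian of f at y, with ∂Γ by central differences."""
        u, v = y[:2], y[2:]
        A = np.zeros((4, 4))
        A[0, 2] = A[1, 3] = 1.0
        gamma = space.christoffel(u, clamp=True)
        # ∂a/∂v
        A[2:, 2:] = -2.0 * np.einsum("kij,i->kj", gamma, v)
        # ∂a/∂u via FD on Γ
        for a in range(2):
            h = space._fd_step(a)
            up, um = u.copy(), u.copy()
            up[a] += h
            um[a] -= h
            gp = space.christoffel(up, clamp=True)
            gm = space.christoffel(um, clamp=True)
            dgam = (gp - gm) / (2 * h)
            A[2:, a] = -np.einsum("kij,i,j->k", dgam, v, v)
        return A

    def jacobian(Y):
        rows, cols, vals = [], [], []

        def put(r0, c0, block):
            for i in range(block.shape[0]):
                for j in range(block.shape[1]):
                    if block[i, j] != 0.0:
                        rows.append(r0 + i)
                        cols.append(c0 + j)
                        vals.append(block[i, j])

        I4 = np.eye(4)
        for i in range(n - 1):
            Ai = jac_f(Y[i])
            Aip = jac_f(Y[i + 1])
            put(4 * i, 4 * i, -I4 - 0.5 * dt * Ai)
            put(4 * i, 4 * (i + 1), I4 - 0.5 * dt * Aip)
        base = 4 * (n - 1)
        put(base, 0, np.eye(2, 4))
        put(base + 2, 4 * (n - 1), np.eye(2, 4))
        return sp.csc_matrix(
            (vals, (rows, cols)), shape=(4 * n, 4 * n)
        )

    history = []
    r = residuals(Y)
    for it in range(max_iter):
        rmax = float(np.max(np.abs(r)))
        history.append(rmax)
        if rmax < tol:
            break
        J = jacobian(Y)
        try:
            step = spla.spsolve(J, -r)
        except Exception:
            step = spla.lsqr(J, -r)[0]
        if not np.all(np.isfinite(step)):
            step = spla.lsqr(J, -r)[0]
        # damped update: halve until the residual norm decreases
        lam = 1.0
        base_norm = np.linalg.norm(r)
        for _ in range(30):
            Y_new = Y + lam * step.reshape(n, 4)
            r_new = residuals(Y_new)
            if np.linalg.norm(r_new) < base_norm or lam < 1e-8:
                break
            lam *= 0.5
        Y, r = Y_new, r_new
        if lam * float(np.max(np.abs(step))) < step_tol:
            history.append(float(np.max(np.abs(r))))
            break
    rmax = float(np.max(np.abs(r)))
    if rmax > math.sqrt(tol):
        raise ConvergenceError(
            f"residual BVP did not converge: max |r| = {rmax:.3e}",
            best_mismatch=rmax,
            history=history,
        )
    U, V = Y[:, :2], Y[:, 2:]
    # cumulative arc length from metric speed (constant up to discretisation)
    speeds = np.array(
        [space.norm(space.clamp_into_domain(U[i]), V[i]) for i in range(n)]
    )
    ds_seg = 0.5 * (speeds[1:] + speeds[:-1]) * dt
    s = np.concatenate([[0.0], np.cumsum(ds_seg)])
    return GeodesicPath(
        space, U, V, s, method="residual", iterations=len(history), residual=rmax
    )


# ---------------------------------------------------------------------------
# Distance, exp and log maps


def path_length(path: GeodesicPath, ds: float = 0.002) -> float:
    """Sum of per-segment lengths: embedding chords when embedded, else
    √(Δuᵀ g Δu) with the midpoint metric.

    The path is first resampled (cubic in arc length) at spacing ``ds`` so
    the chord sum is insensitive to the solver's native sample count.
    """
    space = path.space
    n = max(len(path.u), int(math.ceil(path.s[-1] / ds)) + 1)
    U = path.resample(np.linspace(0.0, 1.0, n))
    if space.is_embedded:
        pts = np.array([space.point(space.wrap(q)) for q in U])
        return float(np.sum(np.linalg.norm(np.diff(pts, axis=0), axis=1)))
    total = 0.0
    for i in range(n - 1):
        du = U[i + 1] - U[i]
        mid = space.clamp_into_domain(0.5 * (U[i + 1] + U[i]))
        g = space.metric(mid)
        total += math.sqrt(max(du @ g @ du, 0.0))
    return total


def geodesic_distance(
    space: Space, uA, uB, method: str = "shoot", **kwargs
) -> float:
    """Length of the BVP geodesic between two points.

    Uses the first converged geodesic found by the chosen solver (no global
    minimisation over multiple geodesics).
    """
    if method == "shoot":
        path = geodesic_bvp_shoot(space, uA, uB, **kwargs)
    elif method == "residual":
        path = geodesic_bvp_residual(space, uA, uB, **kwargs)
    else:
        raise ValueError(f"unknown BVP method {method!r}")
    return path_length(path)


def exp_map(space: Space, u0, X, ds: float = DS_DEFAULT) -> np.ndarray:
    """Endpoint of the geodesic with initial velocity X (length |X|_g)."""
    X = np.asarray(X, dtype=float)
    l = space.norm(space.wrap(np.asarray(u0, dtype=float)), X)
    if l < 1e-14:
        return np.array(u0, dtype=float)
    return geodesic_ivp(space, u0, X, l, ds=ds).end


def log_map(space: Space, u0, u1, ds: float = DS_DEFAULT, **kwargs) -> np.ndarray:
    """Initial velocity X with |X|_g = d(u0, u1) and exp(u0, X) = u1."""
    path = geodesic_bvp_shoot(space, u0, u1, ds=ds, **kwargs)
    return path.start_tangent * path_length(path)
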