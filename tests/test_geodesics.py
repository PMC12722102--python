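"""Geodesic solvers: IVP integration, BVP shooting/collocation, exp/log."""

import math

import numpy as np
import pytest

import riemls as R
from riemls.geodesics import path_length

from conftest import sphere_clairaut


def great_circle_distance(sph, u, v3_plane_normal):
    """Distance of a sphere chart point to the great circle with the given
    plane normal (analytic oracle)."""
    p = sph.point(sph.wrap(u))
    return abs(p @ v3_plane_normal)


class TestIVP:
    def test_plane_straight_line(self, plane):
        p = R.geodesic_ivp(plane, (0, 0), (1, 0), 1.0)
        assert np.allclose(p.end, [1, 0], atol=1e-12)
        assert np.allclose(p.end_tangent, [1, 0], atol=1e-12)

    def test_sphere_equator_to_pole(self, sphere):
        p = R.geodesic_ivp(sphere, (math.pi / 2, 0.3), (-1.0, 0.0),
                           math.pi / 2, ds=0.01)
        assert abs(p.end[0]) < 1e-4  # colatitude ~ 0: the north pole

    def test_sphere_path_stays_on_great_circle(self, sphere):
        u0 = np.array([1.1, 0.4])
        d0 = np.array([0.3, 1.0])
        path = R.geodesic_ivp(sphere, u0, d0, 2.5, ds=0.01)
        # oracle: the great circle through S(u0) with tangent d0 pushed forward
        P = sphere.point(u0)
        T = sphere.pushforward(u0, d0)
        n = np.cross(P, T)
        n /= np.linalg.norm(n)
        devs = [great_circle_distance(sphere, u, n) for u in path.u]
        assert max(devs) < 1e-4

    def test_poincare_geodesic_is_circle_on_x_axis(self, poincare):
        path = R.geodesic_ivp(poincare, (0.0, 1.0), (1.0, 0.0), 2.0)
        radii = np.hypot(path.u[:, 0], path.u[:, 1])
        assert np.max(np.abs(radii - 1.0)) < 1e-4

    def test_unit_speed_conserved(self, sphere):
        path = R.geodesic_ivp(sphere, (1.2, 0.2), (0.4, 1.0), 5.0, ds=0.01)
        for u, v in zip(path.u[::25], path.v[::25]):
            assert abs(sphere.norm(sphere.wrap(u), v) - 1.0) < 1e-6

    def test_speed_drift_small_without_renormalisation(self, sphere):
        path = R.geodesic_ivp(sphere, (1.2, 0.2), (0.4, 1.0), 10.0,
                              n_steps=1000, renormalize=False)
        drift = abs(sphere.norm(sphere.wrap(path.u[-1]), path.v[-1]) - 1.0)
        assert drift < 1e-4

    def test_boundary_exit_carries_last_sample(self):
        pin = R.Pin(1.0, 0.2, 2.0, 1.0)  # short chart: exits the bottom
        with pytest.raises(R.BoundaryError) as err:
            R.geodesic_ivp(pin, (0.0, 0.0), (-1.0, 0.0), 10.0)
        assert err.value.last_valid is not None
        u_last, v_last = err.value.last_valid
        assert pin.contains(u_last, tol=0.05)  # within the step tolerance

    def test_zero_direction_rejected(self, plane):
        with pytest.raises(ValueError):
            R.geodesic_ivp(plane, (0, 0), (0, 0), 1.0)


class TestClairaut:
    def test_ellipsoid_invariant_with_bounce_back(self):
        ell = R.Ellipsoid(1.0, 1.0, 1.6)
        path = R.geodesic_ivp(ell, (math.pi / 2, 0.0), (0.35, 1.0), 20.0,
                              ds=0.01)
        c = sphere_clairaut(ell, path)
        assert np.max(np.abs(c - c[0])) / abs(c[0]) < 1e-4
        # the band: sin(beta) reaches 1 at the turning colatitudes
        r = np.array([ell.revolution_radius(ell.wrap(u)) for u in path.u])
        assert np.min(r) == pytest.approx(abs(c[0]), rel=1e-3)

    def test_pin_invariant_and_coiling_bounce(self):
        pin = R.Pin(1.0, 0.2, 2.0, 10.0)
        path = R.geodesic_ivp(pin, (-1.0, 0.0), (1.0, 3.0), 20.0, ds=0.01)
        c = sphere_clairaut(pin, path)
        assert np.max(np.abs(c - c[0])) / abs(c[0]) < 1e-4
        # Clairaut invariant ~0.93 exceeds the neck radius 0.2: the path must
        # turn back below the neck (never reaches the thin section)
        assert abs(c[0]) > pin.r_neck
        assert np.max(path.u[:, 0]) < 0.5

    def test_pin_neck_crossing_appears_below_clairaut_bound(self):
        pin = R.Pin(1.0, 0.2, 2.0, 10.0)
        path = R.geodesic_ivp(pin, (-1.0, 0.0), (1.0, 0.1), 12.0, ds=0.01)
        c = sphere_clairaut(pin, path)
        assert abs(c[0]) < pin.r_neck  # below the bound ...
        assert np.max(path.u[:, 0]) > 2.0  # ... so it passes the neck

    def test_pseudosphere_invariant_with_bounce(self):
        ps = R.Pseudosphere(1.0, t_range=(0.02, 10.0))
        path = R.geodesic_ivp(ps, (1.0, 0.0), (1.0, 0.15), 4.0, ds=0.01)
        c = sphere_clairaut(ps, path)
        assert np.max(np.abs(c - c[0])) / abs(c[0]) < 1e-4
        r = np.array([ps.revolution_radius(u) for u in path.u])
        assert np.min(r) == pytest.approx(abs(c[0]), rel=1e-3)  # sinβ → 1


class TestBVP:
    def test_plane_three_four_five(self, plane):
        for method in (R.geodesic_bvp_shoot, R.geodesic_bvp_residual):
            path = method(plane, (0.0, 0.0), (3.0, 4.0))
            assert path_length(path) == pytest.approx(5.0, abs=1e-6)
            assert np.allclose(path.end, [3, 4], atol=1e-6)

    def test_sphere_equator_quarter_arc(self, sphere):
        a, b = (math.pi / 2, 0.0), (math.pi / 2, math.pi / 2)
        for method in (R.geodesic_bvp_shoot, R.geodesic_bvp_residual):
            path = method(sphere, a, b)
            assert path_length(path) == pytest.approx(math.pi / 2, abs=1e-3)

    def test_poincare_vertical_segment(self, poincare):
        path = R.geodesic_bvp_shoot(poincare, (0.0, 1.0), (0.0, 2.0))
        assert path_length(path) == pytest.approx(math.log(2), abs=1e-3)
        assert np.max(np.abs(path.u[:, 0])) < 1e-3  # stays vertical

    def test_poincare_symmetric_arc(self, poincare):
        path = R.geodesic_bvp_residual(poincare, (-1.0, 1.0), (1.0, 1.0))
        # oracle: circle centred on the x-axis through both points: centre 0,
        # radius sqrt(2)
        radii = np.hypot(path.u[:, 0], path.u[:, 1])
        assert np.max(np.abs(radii - math.sqrt(2))) < 1e-3

    def test_residual_plane_equally_spaced(self, plane):
        path = R.geodesic_bvp_residual(plane, (0.0, 0.0), (1.0, 0.0),
                                       n_points=11)
        assert np.allclose(path.u[:, 0], np.linspace(0, 1, 11), atol=1e-9)
        assert np.allclose(path.u[:, 1], 0.0, atol=1e-9)

    def test_solvers_agree_on_seeded_pairs(self, sphere, poincare, torus):
        rng = np.random.default_rng(11)
        cases = {
            "sphere": (sphere, [0.8, 0.0], [0.8, 1.5]),
            "torus": (torus, [0.0, 0.0], [2.2, 2.2]),
            "poincare": (poincare, [-1.5, 0.5], [1.5, 2.5]),
        }
        fr = np.linspace(0, 1, 40)
        for name, (space, lo, hi) in cases.items():
            for _ in range(5):
                u0 = rng.uniform(lo, hi)
                u1 = rng.uniform(lo, hi)
                if np.linalg.norm(u1 - u0) < 0.2:
                    continue
                ps = R.geodesic_bvp_shoot(space, u0, u1)
                pr = R.geodesic_bvp_residual(space, u0, u1)
                gap = np.max(np.abs(ps.resample(fr) - pr.resample(fr)))
                assert gap < 1e-3, name
                assert abs(path_length(ps) - path_length(pr)) < 1e-4, name

    def test_nonconvergence_raises_with_best_mismatch(self, sphere):
        with pytest.raises(R.ConvergenceError) as err:
            # unreachable within the allowed length budget
            R.geodesic_bvp_shoot(sphere, (1.5, 0.0), (1.5, 3.0), l_max=0.01)
        assert err.value.best_mismatch is not None


class TestDistanceExpLog:
    def test_plane_distance(self, plane):
        assert R.geodesic_distance(plane, (0, 0), (3, 4)) == pytest.approx(
            5.0, abs=1e-6
        )

    def test_poincare_closed_form_distance(self, poincare):
        d = R.geodesic_distance(poincare, (0.0, 1.0), (0.0, 8.0))
        assert d == pytest.approx(math.log(8), abs=1e-3)

    def test_distance_symmetry(self, sphere):
        a, b = (1.0, 0.5), (1.8, 1.8)
        dab = R.geodesic_distance(sphere, a, b)
        dba = R.geodesic_distance(sphere, b, a)
        assert dab == pytest.approx(dba, abs=1e-5)

    def test_exp_of_zero_is_identity(self, sphere):
        assert np.allclose(R.exp_map(sphere, (1.0, 1.0), (0.0, 0.0)),
                           [1.0, 1.0])

    def test_plane_log_is_displacement(self, plane):
        assert np.allclose(R.log_map(plane, (0, 0), (2, 1)), [2, 1], atol=1e-6)

    def test_sphere_log_norm_is_distance(self, sphere):
        X = R.log_map(sphere, (math.pi / 2, 0.0), (math.pi / 2, math.pi / 2))
        assert sphere.norm((math.pi / 2, 0.0), X) == pytest.approx(
            math.pi / 2, abs=1e-3
        )

    def test_exp_log_inversion_random_pairs(self, sphere):
        rng = np.random.default_rng(5)
        for _ in range(5):
            u0 = rng.uniform([0.9, 0.0], [2.1, 2.0])
            u1 = rng.uniform([0.9, 0.0], [2.1, 2.0])
            if np.linalg.norm(u1 - u0) < 0.2:
                continue
            X = R.log_map(sphere, u0, u1)
            back = R.exp_map(sphere, u0, X)
            assert np.max(np.abs(back - u1)) < 1e-4


class TestDeviation:
    @staticmethod
    def _rotate90(space, u, h, sign):
        B = space.orthonormal_basis(space.wrap(np.asarray(u, float)))
        c = np.linalg.solve(B, np.asarray(h, float))
        return B @ (sign * np.array([-c[1], c[0]]))

    def _initially_parallel_separation(self, space, u0, h0, eps, s):
        """Launch two geodesics that are initially parallel: the second
        starts at the end of a geodesic connector orthogonal to the first
        heading, with its heading orthogonal to the connector."""
        u0 = np.asarray(u0, float)
        h0 = np.asarray(h0, float) / space.norm(space.wrap(u0), h0)
        conn = R.geodesic_ivp(space, u0, self._rotate90(space, u0, h0, +1), eps)
        hB = self._rotate90(space, conn.end, conn.end_tangent, -1)
        a = R.geodesic_ivp(space, u0, h0, s)
        b = R.geodesic_ivp(space, conn.end, hB, s)
        end_sep = np.linalg.norm(
            space.point(space.wrap(a.end)) - space.point(space.wrap(b.end))
        )
        return end_sep / eps

    def test_parallel_geodesics_converge_on_sphere(self):
        ratio = self._initially_parallel_separation(
            R.Sphere(1.0), (1.4, 0.2), (-0.3, 1.0), 0.02, 1.0
        )
        # Jacobi: J(s)/J(0) = cos(s) ~ 0.54 at s = 1
        assert ratio == pytest.approx(math.cos(1.0), abs=0.02)

    def test_parallel_geodesics_diverge_on_pseudosphere(self):
        ratio = self._initially_parallel_separation(
            R.Pseudosphere(1.0, t_range=(0.05, 6.0)), (1.2, 0.0), (1.0, 0.1),
            0.02, 1.0,
        )
        # Jacobi: J(s)/J(0) = cosh(s) ~ 1.54 at s = 1
        assert ratio > 1.2


class TestPathExport:
    def test_csv_round_trip(self, sphere, tmp_path):
        path = R.geodesic_ivp(sphere, (1.0, 0.0), (0.2, 1.0), 1.0, n_steps=20)
        f = tmp_path / "path.csv"
        path.to_csv(str(f))
        data = np.loadtxt(f, delimiter=",", skiprows=1)
        assert data.shape == (21, 8)  # s,p,q,dp,dq,x,y,z
        assert np.allclose(data[:, 1:3], path.u, atol=1e-12)
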