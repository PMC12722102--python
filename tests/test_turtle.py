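"""Riemannian turtle: moves, turns, stack, transport, modes, orchestration."""

import math

import numpy as np
import pytest

import riemls as R
from riemls.gallery import build

from conftest import uv_from_xyz


def arrow_angle_about_normal(space, item0, item1, u_end):
    """Signed angle from arrow0 to arrow1 about the surface normal at u_end."""
    w0 = item0.xyz[1] - item0.xyz[0]
    w1 = item1.xyz[1] - item1.xyz[0]
    U = space.normal(space.wrap(u_end))
    return math.atan2(float(np.cross(w0, w1) @ U), float(w0 @ w1))


class TestBasics:
    def test_forward_on_plane(self, plane):
        t = R.RiemannianTurtle(plane)
        t.execute("F(1)")
        assert np.allclose(t.state.u, [1, 0], atol=1e-12)

    def test_turn_quarter_left(self, plane):
        t = R.RiemannianTurtle(plane)
        t.turn(90)
        assert np.allclose(t.state.h, [0, 1], atol=1e-12)

    def test_full_turn_restores_heading_and_advances_alpha(self, sphere):
        t = R.RiemannianTurtle(sphere, u0=(1.0, 1.0), h0=(1.0, 0.3))
        h_before = t.state.h.copy()
        t.turn(360)
        assert np.allclose(t.state.h, h_before, atol=1e-9)
        assert t.state.alpha_c == pytest.approx(2 * math.pi)

    def test_turn_preserves_metric_norm_in_scaled_metric(self):
        pc = R.PoincareHalfPlane()
        t = R.RiemannianTurtle(pc, u0=(0.0, 2.0), h0=(1.0, 0.0))
        assert pc.norm(t.state.u, t.state.h) == pytest.approx(1.0)
        t.turn(37)
        assert pc.norm(t.state.u, t.state.h) == pytest.approx(1.0, abs=1e-12)

    def test_metric_norm_preserved_through_long_sequences(self, sphere):
        t = R.RiemannianTurtle(sphere, u0=(1.3, 0.0), h0=(0.2, 1.0))
        t.execute("F(0.4)+(33)F(0.2)-(120)F(0.5)+(77)F(0.3)")
        n = sphere.norm(sphere.wrap(t.state.u), t.state.h)
        assert abs(n - 1.0) < 1e-6

    def test_sphere_forward_reaches_pole(self, sphere):
        t = R.RiemannianTurtle(sphere, u0=(math.pi / 2, 0.0), h0=(-1.0, 0.0))
        t.execute(f"F({math.pi / 2:.17g})")
        assert abs(t.state.u[0]) < 1e-4

    def test_ellipsoid_forward_steps_conserve_clairaut(self):
        from conftest import sphere_clairaut

        ell = R.Ellipsoid(1.0, 1.0, 1.6)
        t = R.RiemannianTurtle(ell, u0=(math.pi / 2, 0.0), h0=(0.35, 1.0))
        cs = []
        for _ in range(6):
            path = t.forward(1.0)
            cs.append(sphere_clairaut(ell, path))
        c = np.concatenate(cs)
        assert np.max(np.abs(c - c[0])) / abs(c[0]) < 1e-4


class TestStack:
    def test_branch_leaves_outer_state_unchanged(self, sphere):
        t = R.RiemannianTurtle(sphere, u0=(1.2, 0.5), h0=(0.3, 1.0))
        u0, h0 = t.state.u.copy(), t.state.h.copy()
        t.execute("[F(1)+(45)F(0.3)]")
        assert np.array_equal(t.state.u, u0)
        assert np.array_equal(t.state.h, h0)

    def test_nested_restores_lifo(self, plane):
        t = R.RiemannianTurtle(plane)
        t.execute("F(1)[+(90)F(1)[+(90)F(1)]F(1)]")
        assert np.allclose(t.state.u, [1, 0], atol=1e-12)

    def test_alpha_c_does_not_leak_from_branch(self, sphere):
        t = R.RiemannianTurtle(sphere, u0=(1.2, 0.5), h0=(0.3, 1.0))
        t.turn(30)
        a = t.state.alpha_c
        t.execute("[+(90)F(0.2)+(45)]")
        assert t.state.alpha_c == a

    def test_pop_empty_stack_raises(self, plane):
        t = R.RiemannianTurtle(plane)
        with pytest.raises(R.StackError):
            t.pop()

    def test_stack_neutrality_of_bracketed_insert(self, sphere):
        s1, s2, s3 = "F(0.4)+(25)", "F(0.7)-(40)F(0.2)", "F(0.3)-(15)F(0.5)"
        ta = R.RiemannianTurtle(sphere, u0=(1.2, 0.0), h0=(0.4, 1.0))
        ta.execute(s1 + "[" + s2 + "]" + s3)
        tb = R.RiemannianTurtle(sphere, u0=(1.2, 0.0), h0=(0.4, 1.0))
        tb.execute(s1 + s3)
        assert np.allclose(ta.state.u, tb.state.u, atol=1e-12)
        assert np.allclose(ta.state.h, tb.state.h, atol=1e-12)


class TestFlatRegression:
    """On the plane the Riemannian turtle must reproduce a classical
    Euclidean turtle vertex-for-vertex."""

    @pytest.mark.parametrize("program", ["flat_spiral", "flat_random_walk",
                                         "flat_koch", "flat_tree"])
    def test_matches_euclidean_reference(self, program, euclid_turtle_cls):
        from riemls.lsystem import interpret_string
        from riemls.turtle import RiemannianTurtle, run

        prog = build(program)
        scene, final = run(prog)
        commands = interpret_string(final, prog.irules,
                                    keep=RiemannianTurtle.COMMANDS)
        ref = euclid_turtle_cls().execute(
            [(m.name, m.params) for m in commands]
        )
        got = [(it.uv[0], it.uv[-1]) for it in scene.polylines()]
        assert len(got) == len(ref.segments)
        for (a, b), (ca, cb) in zip(got, ref.segments):
            assert abs(complex(a[0], a[1]) - ca) < 1e-9
            assert abs(complex(b[0], b[1]) - cb) < 1e-9


class TestParallelTransport:
    def test_arrow_keeps_constant_angle_along_single_geodesic(self, sphere):
        t = R.RiemannianTurtle(sphere, u0=(1.3, 0.2), h0=(0.4, 1.0))
        t.parallel_transport_reset()
        a0 = t.transported_arrow(30.0, 0.2)
        t.execute("F(0.8)")
        a1 = t.transported_arrow(30.0, 0.2)
        # with no turns, the arrow keeps a 30° angle to the local heading
        H = sphere.pushforward(sphere.wrap(t.state.u), t.state.h)
        H /= np.linalg.norm(H)
        w1 = a1.xyz[1] - a1.xyz[0]
        w1 /= np.linalg.norm(w1)
        assert math.degrees(math.acos(np.clip(w1 @ H, -1, 1))) == pytest.approx(
            30.0, abs=1e-5
        )

    def test_flat_loop_has_zero_angle_defect(self, plane):
        t = R.RiemannianTurtle(plane)
        t.parallel_transport_reset()
        a0 = t.transported_arrow(0.0, 0.3)
        t.execute("F(1)+(90)F(1)+(90)F(1)+(90)F(1)+(90)")
        a1 = t.transported_arrow(0.0, 0.3)
        w0 = a0.uv[1] - a0.uv[0]
        w1 = a1.uv[1] - a1.uv[0]
        ang = math.atan2(w0[0] * w1[1] - w0[1] * w1[0], w0 @ w1)
        assert abs(ang) < 1e-9

    def test_octant_angle_defect_is_quarter_turn(self, sphere):
        c, s = math.cos(0.6), math.sin(0.6)
        v1 = np.array([c, 0.0, -s])
        u1 = uv_from_xyz(v1)
        h0 = np.linalg.lstsq(sphere.jacobian(u1), [0.0, 1.0, 0.0],
                             rcond=None)[0]
        t = R.RiemannianTurtle(sphere, u0=u1, h0=h0)
        t.parallel_transport_reset()
        a0 = t.transported_arrow(0.0, 0.25)
        t.execute((f"F({math.pi / 2:.17g})+(90)") * 3)
        a1 = t.transported_arrow(0.0, 0.25)
        defect = arrow_angle_about_normal(sphere, a0, a1, t.state.u)
        assert defect == pytest.approx(math.pi / 2, abs=1e-3)

    def test_random_small_triangles_match_spherical_excess(self, sphere):
        rng = np.random.default_rng(8)
        for _ in range(4):
            # random geodesic triangle: start point, two side lengths, angle
            u0 = rng.uniform([1.0, 0.5], [2.0, 2.5])
            t = R.RiemannianTurtle(sphere, u0=u0, h0=rng.normal(size=2))
            l1, l2 = rng.uniform(0.3, 0.8, size=2)
            A = sphere.point(sphere.wrap(t.state.u))
            t.forward(l1)
            B = sphere.point(sphere.wrap(t.state.u))
            interior = rng.uniform(50.0, 110.0)
            t.turn(180.0 - interior)  # exterior turn, interior angle at B
            t.forward(l2)
            C = sphere.point(sphere.wrap(t.state.u))
            # oracle: spherical excess vs the holonomy the turtle measures
            excess = _spherical_excess(A, B, C)
            defect = _triangle_holonomy(sphere, A, B, C)
            # |defect| = excess; the sign flips with traversal orientation
            assert abs(defect) == pytest.approx(excess, abs=1e-3)


def _spherical_excess(A, B, C):
    """Brute-force spherical triangle area (unit sphere) via corner angles."""
    ang = 0.0
    for P, Q, S in [(A, B, C), (B, C, A), (C, A, B)]:
        u = Q - (Q @ P) * P
        v = S - (S @ P) * P
        ang += math.acos(
            np.clip(u @ v / (np.linalg.norm(u) * np.linalg.norm(v)), -1, 1)
        )
    return ang - math.pi


def _triangle_holonomy(sphere, A, B, C):
    """Walk the closed triangle A->B->C->A with a transported arrow and
    return the measured angle defect."""
    uA = uv_from_xyz(A / np.linalg.norm(A))
    t = R.RiemannianTurtle(sphere, u0=uA,
                           h0=R.log_map(sphere, uA, uv_from_xyz(B / np.linalg.norm(B))))
    t.parallel_transport_reset()
    a0 = t.transported_arrow(0.0, 0.2)
    for target in (B, C, A):
        uT = uv_from_xyz(target / np.linalg.norm(target))
        t.line_to(uT, method="shoot")
    # rotate heading back to the initial direction so only transport remains
    X0 = R.log_map(sphere, uA, uv_from_xyz(B / np.linalg.norm(B)))
    from riemls.fields import signed_angle_to

    t.turn(math.degrees(signed_angle_to(sphere, t.state.u, t.state.h, X0)))
    a1 = t.transported_arrow(0.0, 0.2)
    return arrow_angle_about_normal(sphere, a0, a1, t.state.u)


class TestLineTo:
    def test_plane_line_to(self, plane):
        t = R.RiemannianTurtle(plane)
        path = t.line_to((3.0, 4.0))
        assert np.allclose(t.state.u, [3, 4], atol=1e-6)
        assert R.path_length(path) == pytest.approx(5.0, abs=1e-6)

    def test_round_trip_returns_with_reversed_heading(self, sphere):
        A, B = (1.2, 0.3), (1.7, 1.1)
        t = R.RiemannianTurtle(sphere, u0=A, h0=(1.0, 0.0))
        t.line_to(B)
        h_at_B = t.state.h.copy()
        t.line_to(A)
        assert np.max(np.abs(t.state.u - A)) < 1e-3
        # heading at A is opposite to the original outgoing log direction
        out = R.log_map(sphere, A, B)
        out /= sphere.norm(A, out)
        assert np.allclose(-t.state.h, out, atol=1e-2)


class TestModes:
    def test_end_space_escapes_along_tangent(self, sphere):
        t = R.RiemannianTurtle(sphere, u0=(math.pi / 2, 0.0), h0=(0.0, 1.0))
        t.end_space()
        t.forward(2.0)
        # heading at the equator point (1,0,0) moving east is +y
        assert np.allclose(t.state.e_pos, [1.0, 2.0, 0.0], atol=1e-9)

    def test_end_space_in_abstract_space_fails(self, poincare):
        t = R.RiemannianTurtle(poincare, u0=(0.0, 1.0), h0=(1.0, 0.0))
        with pytest.raises(R.ModeError):
            t.end_space()

    def test_indirect_square_closes_direct_square_does_not(self, sphere):
        direct = R.RiemannianTurtle(sphere, u0=(math.pi / 2, 0.0), h0=(0.0, 1.0))
        direct.execute("F(1)+(90)F(1)+(90)F(1)+(90)F(1)")
        gap = np.linalg.norm(
            sphere.point(sphere.wrap(direct.state.u))
            - sphere.point((math.pi / 2, 0.0))
        )
        assert gap > 0.1

        ind = R.RiemannianTurtle(sphere, u0=(math.pi / 2, 0.0), h0=(0.0, 1.0))
        ind.execute("StartIndirect F(1)+(90)F(1)+(90)F(1)+(90)F(1) StopIndirect")
        assert np.allclose(ind.state.u, [math.pi / 2, 0.0], atol=1e-12)

    def test_indirect_requires_embedding(self, poincare):
        t = R.RiemannianTurtle(poincare, u0=(0.0, 1.0), h0=(1.0, 0.0))
        with pytest.raises(R.ModeError):
            t.indirect_begin()

    def test_unbalanced_indirect_end_fails(self, sphere):
        t = R.RiemannianTurtle(sphere, u0=(1.0, 1.0), h0=(1.0, 0.0))
        with pytest.raises(R.ModeError):
            t.indirect_end()


class TestStaticF:
    def _patch(self):
        xs, ys = np.meshgrid(np.linspace(0, 1, 6), np.linspace(0, 1, 6),
                             indexing="ij")
        ctrl = np.stack([xs, ys, np.zeros_like(xs)], axis=-1)
        return R.BSplinePatch(ctrl.copy(), degree=(3, 3))

    def test_replay_identical_on_unchanged_surface(self):
        patch = self._patch()
        t = R.RiemannianTurtle(patch, u0=(0.2, 0.2), h0=(1.0, 0.4))
        t.execute("StaticF(seg1,0.5)")
        first = t.scene.items[-1]
        t2 = R.RiemannianTurtle(patch, u0=(0.2, 0.2), h0=(1.0, 0.4))
        t2.static_cache = t.static_cache
        t2.execute("StaticF(seg1,0.5)")
        second = t2.scene.items[-1]
        assert np.array_equal(first.uv, second.uv)
        assert np.allclose(first.xyz, second.xyz)

    def test_replay_tracks_deformed_surface(self):
        patch = self._patch()
        t = R.RiemannianTurtle(patch, u0=(0.2, 0.2), h0=(1.0, 0.4))
        t.execute("StaticF(seg1,0.5)")
        before = t.scene.items[-1]
        patch.control[:, :, 2] += 0.3 * patch.control[:, :, 0]  # tilt the patch
        t.state.u = np.array([0.2, 0.2])
        t.state.h = np.array([1.0, 0.4])
        t.execute("StaticF(seg1,0.5)")
        after = t.scene.items[-1]
        assert np.array_equal(before.uv, after.uv)  # material (uv) samples fixed
        assert not np.allclose(before.xyz, after.xyz)  # 3-D positions moved

    def test_key_reuse_with_different_length_fails(self):
        patch = self._patch()
        t = R.RiemannianTurtle(patch, u0=(0.2, 0.2), h0=(1.0, 0.0))
        t.execute("StaticF(k,0.3)")
        with pytest.raises(R.CacheError):
            t.execute("StaticF(k,0.4)")

    def test_fresh_key_recomputes(self):
        patch = self._patch()
        t = R.RiemannianTurtle(patch, u0=(0.2, 0.2), h0=(1.0, 0.0))
        t.execute("StaticF(a,0.3)")
        t.static_cache.clear()
        t.execute("StaticF(a,0.3)")
        assert "a" in t.static_cache


class TestRun:
    def test_zero_steps_interprets_axiom(self, plane):
        prog = R.LsystemProgram(axiom=R.LString("F(1)+(90)F(1)"), space=plane)
        scene, final = R.run(prog)
        assert len(scene.polylines()) == 2
        assert str(final) == "F(1)+(90)F(1)"

    def test_spiral_segments_grow_monotonically(self):
        scene, _ = R.run(build("flat_spiral"))
        lengths = [
            np.linalg.norm(it.uv[-1] - it.uv[0]) for it in scene.polylines()
        ]
        assert all(b > a for a, b in zip(lengths, lengths[1:]))

    def test_koch_on_torus_stays_on_torus(self):
        prog = build("koch_torus")
        scene, _ = R.run(prog)
        tor = prog.space
        for it in scene.polylines():
            # |p - R*p_hat| = r for every 3-D sample (on-torus audit)
            xy = it.xyz[:, :2]
            ring = xy / np.linalg.norm(xy, axis=1, keepdims=True)
            d = it.xyz - np.column_stack([ring, np.zeros(len(it.xyz))])
            assert np.allclose(np.linalg.norm(d, axis=1), tor.r, atol=1e-9)
        # connected: consecutive segments share endpoints
        polys = scene.polylines()
        for a, b in zip(polys, polys[1:]):
            assert np.allclose(a.xyz[-1], b.xyz[0], atol=1e-9)

    def test_run_deterministic_under_seed(self):
        s1, _ = R.run(build("flat_random_walk"), seed=9)
        s2, _ = R.run(build("flat_random_walk"), seed=9)
        s3, _ = R.run(build("flat_random_walk"), seed=10)
        assert s1.checksum() == s2.checksum()
        assert s1.checksum() != s3.checksum()
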