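# Methods

This note records the mathematical procedures implemented in `riemls`, the
defaults and tolerances that matter, the choices made where several
formulations were possible, and the known limitations.

## Spaces

A space is a 2-D Riemannian manifold described in a single coordinate chart
over a rectangle with per-axis periodicity flags. Two families exist:

**Embedded parametric surfaces** carry an immersion `S(p, q) → R³`. The
covariant basis `S_p, S_q` gives the metric `g_ij = S_i · S_j`, the unit
normal `n = S_p × S_q / |·|`, the second fundamental form
`II_ij = S_ij · n`, the shape operator `g⁻¹ II` (principal curvatures as its
eigenvalues, positive when the surface bends toward `+n`), `K = det II /
det g` and `H = ½ tr(g⁻¹ II)`. Christoffel symbols use the embedding route
`Γ^k_ij = g^{kl} (S_ij · S_l)`. All built-in surfaces (plane, sphere,
ellipsoid, torus, tractoid "pseudosphere", generic surface of revolution,
pin-shaped funnel, egg-box, tensor-product B-spline patch) supply analytic
first and second partials except the spline patch, whose second partials
are finite differences of analytic first derivatives.

**Abstract metric spaces** supply only `g11, g12, g22` as functions of
`(p, q)` (plus optional analytic first derivatives). Everything is
intrinsic: the Levi-Civita connection
`Γ^k_ij = ½ g^{kl} (∂_i g_jl + ∂_j g_il − ∂_l g_ij)` and the Brioschi
formula for `K`. For embedded surfaces the intrinsic route is also
available and must agree with the embedding route (Gauss's theorem); the
acceptance suite checks max |Δ| < 1e-6 on 20×20 interior grids over every
built-in surface.

Finite differences use central stencils with step `h = 1e-5 × max(1,
domain extent)` per axis; with the smooth metrics used here that keeps
truncation near 1e-9 except very close to chart degeneracies.

**Coordinate conventions.** Sphere and ellipsoid use colatitude
`θ ∈ (0, π)` and periodic azimuth; both torus angles are periodic; angles
are radians internally and degrees at the command surface. Chart-degenerate
loci (sphere poles, the tractoid rim) raise a typed error on evaluation
within `ε = 1e-8`; geodesic integration instead clamps the coordinate to
the locus ± ε, which is what lets a meridian geodesic terminate exactly at
a pole. The tractoid rim is a genuine cuspidal edge of the surface, not
just of the chart: no non-meridian geodesic can be continued past it, which
bounds usable arc length on the pseudosphere (see "fixtures" below).

The distance-sourced abstract metrics are conformal,
`g_ij = f(d)² δ_ij` with `d` the Euclidean distance to a centre point and
`f` either affine increasing (`a + b·d`: forms near the centre curve
strongly) or inverse (`a + b/(1+d)`: geodesics bend away from the source —
shadow avoidance). The specific `f` shapes are this package's
reconstruction of qualitative descriptions; constants are exposed as
parameters.

## Geodesics

**IVP.** `ü^k = −Γ^k_ij u̇^i u̇^j` integrated by classical fixed-step RK4
with `n_steps = max(10, ⌈length/ds⌉)`, `ds = 0.01` by default. Fixed
stepping (rather than adaptive `solve_ivp`) keeps sample counts
deterministic for the turtle and for golden-file regression. The initial
velocity is normalised to unit metric speed, so paths are arc-length
parameterised; the velocity is renormalised after every step (drift control
— with renormalisation off, speed drift stays below 1e-4 over length 10 at
1e3 steps, the expected RK4 order). Leaving a non-periodic domain raises a
boundary error carrying the partial path; the turtle can optionally stop at
the rim instead (`clip_boundary`).

**BVP, shooting.** Minimise the endpoint mismatch over launch angle ψ
(measured in the Gram–Schmidt orthonormal tangent basis) and arc length l
with bounded least squares (`scipy.optimize.least_squares`), multi-start
over 8 evenly spaced angles, accepting squared mismatch < 1e-8. Mismatch is
measured in the embedding when one exists, else in lifted parameter
coordinates. Because the embedding mismatch accepts any periodic
representative of the target, a converged path whose endpoint lies on a
different winding than the lifted target triggers one re-solve against
lifted parameter coordinates. `l_max` defaults to 4× the metric length of
the parameter-space chord (configurable).

**BVP, collocation.** The affinely parameterised equation on `t ∈ [0, 1]`
(constant speed ⇒ arc length is recovered afterwards) discretised with the
trapezoidal rule, endpoint positions clamped, `n_points = 41`. Solved by
damped Newton (halving line search, ≤ 50 iterations) with an analytic
block-sparse Jacobian (`∂Γ/∂u` by central differences), converging when
max |r| < 1e-8 or the step falls below 1e-10; a singular system falls back
to least-squares steps. The initial guess is linear interpolation in
parameter space.

**Distance, exp, log.** Path length is a chord sum after cubic resampling
at spacing 0.002 (embedding chords, or midpoint-metric `√(Δuᵀ g Δu)` for
abstract spaces); the resampling makes the sum insensitive to the solver's
native sample count, which matters when comparing the two solvers at the
1e-4 level. `exp` is the IVP endpoint; `log` is the shooting solution's
initial tangent scaled by the path length. Both BVP solvers return the
first converged solution; no global minimisation over multiple geodesics is
attempted. Between points farther apart than the injectivity radius (on the
torus, ≈ π·r for the minor circle) several true geodesics exist and the two
solvers may return different ones — the cross-validation suite therefore
samples torus endpoint pairs with metric separation ≤ 0.8 < π·0.3, the
uniqueness regime; sphere and Poincaré pairs are drawn uniformly.

## The turtle

State: position `u`, heading `h` (unit metric norm, renormalised after
every operation), accumulated turn angle `α_c`, pen, mode, stack. Turns map
`h` into the Gram–Schmidt orthonormal basis built from `(e_p, e_q)`, apply
a rotation matrix, and map back; the basis is positively oriented, so a
positive angle turns toward the left arm `L = U × H` (counterclockwise
about the normal). `F` updates `(u, h)` from the geodesic endpoint — the
heading is parallel-transported by construction. `LineTo` records the
implicit rotation onto the log-map direction in `α_c`, so transport
bookkeeping remains valid across BVP moves.

**Parallel transport.** Between turns the turtle follows geodesics, along
which a transported vector keeps a constant angle to the tangent; the
transported direction is therefore the heading corrected by
`φ_t = φ_0 − α_c`. The sign convention is pinned by the octant test: a
geodesic triangle of three quarter great circles traversed with three +90°
turns returns the arrow rotated by +π/2 about the outward normal, equal to
the enclosed `∫K dA` (Gauss–Bonnet). The canonical octant has a vertex at a
chart pole, so the octant fixture is rotated to keep vertices and sides
away from the poles — the geometry is identical.

**Modes.** Indirect interpretation runs `F`/turns with flat Euclidean
semantics on `(p, q)`, sampling straight uv segments every `ds` and pushing
them through the immersion (convected forms; uv polygons can be recorded
and filled — on-surface filling of direct-mode polygons is not
implemented). `StaticF` caches the uv samples of its first execution per
key and replays them through the *current* immersion thereafter, so a form
drawn on a patch follows the patch's control points when they move.
`EndSpace` seeds a classical 3-D turtle with the surface frame at the
escape point; it is an error on abstract spaces (nothing to escape into).

**Queries.** `?P`, `?H`, `?U` receive position / heading / normal at their
string location during an interpretation pass; `?T` captures the full
state. A derivation step that produced query modules triggers one
interpretation pass before the next derivation (two-phase step), so
productions can read the turtle's environment.

## L-system core

Modules are single characters, with a registry for multi-character command
names (adjacent single-letter modules are written without separators, so
long names must be declared). Rules are host-language callables; a
declaration-order first-match policy resolves conflicts; stochastic
successors receive a seeded `numpy` Generator, making derivations
bit-reproducible. Context patterns cover a single module per side (with
parameter capture): the left context skips complete bracketed branches and
climbs out of the current branch; the right context may enter a following
branch or skip complete branches. Serialisation uses `Name(p1,p2)` text
with floats at 17 significant digits (lossless round-trip). A YAML config
dialect covers the non-procedural subset, with successor parameter
expressions and metric components compiled by sympy under a character
whitelist.

## Geodesic B-splines

Lane–Riesenfeld in midpoint form: one refinement step of degree d inserts
every edge's **geodesic midpoint** (the point at half the arc length of the
collocation BVP path, linearly interpolated between bracketing samples) and
then runs d−1 rounds replacing consecutive pairs by their geodesic
midpoint. In flat space this is exactly classical uniform B-spline
subdivision (the flat oracle agrees to < 1e-6 after 5 steps); on curved
spaces the limit curve is not strictly a B-spline but inherits the
smoothing behaviour (higher degree ⇒ smaller maximum turning angle, checked
on sphere fixtures). Open polygons pin their endpoints (clamped ends),
matching the leaf-outline usage where curves start and end at branch tips.
Midpoint BVPs warm-start from the previous level where available; 5
subdivision steps is the default rendering depth.

## Fields and feedback

The Riemannian gradient raises the coordinate differential with the inverse
metric; analytic and finite-difference differentials agree below 1e-4 on
the test fields. Tropism imposes geodesic curvature proportional to the
misalignment angle: per step, `δ = η·θ·ds` with θ the signed angle from
heading to gradient (positive on the left, measured in the orthonormal
basis), then a geodesic step of length ds; the proportionality constant of
the underlying curvature law is absorbed into η, and the step assumes
curvature ≈ constant over ds. η = 0 reproduces the plain geodesic bitwise.
Curvature-gated random walks draw uniform turn angles on (−180°, 180°],
tentatively execute the step and accept the first endpoint satisfying the
gate, rolling back rejected trials; refusal after `max_tries` is a value,
not an error. Self-avoidance tests exact 2-D segment crossings (plus a
distance tolerance) in uv space with a uniform spatial hash whose cell size
divides periodic axes exactly; stored segments are compared under ±1 period
shifts, and hits whose closest approach lies within an exclusion radius of
the branch point the query emanates from are exempt. uv-space testing is
exact for immersed (non-self-intersecting) surfaces, the only kind built
in.

## Fixtures and scales used by tests and the acceptance script

Test geometry is generated programmatically; there are no data files. The
main fixtures: unit sphere; prolate ellipsoid (1, 1, 1.6); torus (R=1,
r=0.3); tractoid with R=1; pin funnel narrowing from radius 1 to 0.2 over a
tanh profile; egg-box `z = A sin p sin q`; Poincaré half-plane. Clairaut
invariance (`r·sinβ` constant, relative drift < 1e-4) is checked along
length-20 geodesics on the ellipsoid and the pin — both exhibit bounce-back
where `sinβ → 1` — and along a length-4 bouncing geodesic on the
pseudosphere, where the singular rim bounds the available arc length for
any non-meridian geodesic (every such path reaches `r = c ≤ 1` going down).
On the pin, a launch whose invariant exceeds the neck radius must turn back
before the neck and one below it must pass through — the coiling
dichotomy.

The BVP cross-validation suite runs 50 seeded pairs per space in the test
suite and 15 per space in the acceptance script (the script also re-runs
the 100-pair Poincaré distance check); pair counts were sized to keep the
full run near a minute on one CPU while still sampling each space broadly.
Random-pair loops tolerate isolated solver non-convergence by drawing a
replacement pair (bounded attempts), so a particular seed cannot abort the
whole run; the solved-pair count is reported alongside each value.

## Known limitations

* Single chart per space: no atlases, so forms cannot cross chart
  degeneracies (sphere poles) or the tractoid rim; degenerate points are
  handled by typed errors and clamping, not by chart switching.
* BVP solvers return the first converged geodesic; between far-apart points
  with several geodesics the choice is solver-dependent and the distance is
  not guaranteed globally minimal.
* On-surface filling of direct-mode polygons is not implemented (uv-space
  polygon fills only).
* The B-spline patch is polynomial (no rational weights); degenerate or
  self-intersecting control grids are not validated.
* Surfaces that grow during derivation are supported only through the
  `StaticF` caching primitive and indirect interpretation (material uv
  forms); there is no feedback from the drawn structure onto the surface.
* The synthetic study conditions (fixture shapes, field forms, sensitivity
  constants) are reconstructions of qualitative descriptions; tests
  establish the engine's internal correctness against closed forms and
  independent oracles, not fidelity to any particular organism's
  parameters.
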