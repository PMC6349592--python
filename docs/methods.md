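# Methods

`atriflow` quantifies how the morphology of the left atrial appendage (LAA)
alone shapes left-atrial (LA) hemodynamics and blood stasis under atrial
fibrillation (AF). One template atrial chamber receives different donor
appendages, so every simulated difference in washout is attributable to the
appendage shape. This note records the models, the defaults and why, the
numerical choices, and the limits of what the synthetic experiments show.

All lengths are centimetres, times seconds, masses grams; velocities are
cm/s and flowrates cm³/s (= ml/s).

## Synthetic anatomy

Patient meshes are not shipped; the generator replaces them with parametric
geometry whose ground truth is known analytically.

**Appendage.** A circle of radius `r(s)` is swept along a cubic spline with
rotation-minimizing frames (double-reflection method), which avoids twist
artifacts. The radius profile may taper linearly toward the tip (`taper`),
mimicking appendages narrowed distally. Over the last `r_end` of arclength
the radius follows a circular profile down to zero, so the swept surface
closes with a hemispherical cap *at the spline endpoint*. That choice makes
the generator's centerline length L (the spline arclength), the endpoint
distance D, and the tortuosity chi = L/D − 1 exact properties of the
emitted surface, directly comparable with what the geometry module
measures. Volume and lateral area ground truths are fine-quadrature
integrals of the profile (`∫ π r² ds`, `∫ 2π r √(1+r′²) ds`).

Self-intersection is rejected by a clearance test on the spline samples
(non-adjacent samples must stay farther apart than the sum of local tube
radii) — a sufficient condition that is exact for swept tubes.

**Template atrium.** An ellipsoidal chamber (semi-axes 3.4 × 2.8 × 2.5 cm,
volume ≈ 100 ml — a typical adult LA) carries four pulmonary-vein (PV)
tubes of radius 0.55 cm, a mitral-valve (MV) aperture of radius 1.2 cm and
an appendage ostium of radius 0.68 cm. Port rims are projected onto exact
circles. The ostium is placed between the left PVs and the mitral annulus,
where the anatomical LAA orifice sits; this puts the orifice inside the
transiting E-wave flow path, which is what drives appendage exchange when
the wall barely contracts. No reference dimensions exist for such a
template, so these values are the package's own physiologic choices.

**Study set.** `make_study_set(n, seed)` emits appendages whose tortuosity
targets are spaced over [0.015, 0.50] (monotone increasing) and centerline
lengths over [2.3, 3.5] cm, with volumes drawn from [2.0, 2.6] cm³ — a
realistic clinical spread of appendage geometry. With `n = 2` the set
degenerates to one "simple" (chi < 0.1) and one "complex" (chi > 0.3)
appendage.

## Appendage isolation (shape diameter function)

The SDF assigns each face the local object diameter: 30 rays (default) are
cast from the face centroid into a 60° half-angle cone about the inward
normal; hits whose surface normal points the same way as the source are
false intersections and are discarded; surviving lengths are filtered to
within one standard deviation of the median and averaged with weights
inverse to the angle from the cone axis. Ray directions are drawn once per
seed in a canonical frame and rotated into each face's *intrinsic* frame
(first edge direction), making the field exactly pose-invariant.

Clustering is 1-D k-means (k = 4 by default: chamber, veins, appendage,
transition) on log-SDF, regularized by iterated neighbor majority voting,
then split into edge-connected regions. The chamber is the modal region;
regions containing tagged ports (open rims or cap labels) merge into it;
the appendage is the region containing a user hint point, or else the
largest remaining region adjacent to the chamber. The hint mechanism is the
package's explicit substitute for an "anatomical position" rule that cannot
be formalized from the description alone.

## Grafting

The donor ostium rim is registered to the template rim by point-to-point
ICP (nearest-neighbor matching + closed-form Kabsch/Umeyama fit,
principal-axes initialization, optional uniform scale). A rim is nearly a
planar circle, so ICP cannot distinguish the two half-spaces; if the
transformed appendage apex lands inside the chamber the pose is reflected
through the fixed rim plane (a half-turn about an in-plane axis), which
maps the circular rim onto itself while making the appendage point
outward. By default donors are *not* scaled, preserving their geometric
descriptors; the perimeter mismatch is absorbed by the seam band (a
warning fires beyond a 3× ratio).

Stitching is a greedy zipper loft between the two original rims: the
traversal direction is chosen so the composite is consistently oriented
(no directed edge used twice) and the band is free of real
self-intersections (checked edge-against-triangle); the zipper then
advances along whichever rim yields the shorter diagonal. Vertices within
two rings of the seam are relaxed by Laplacian smoothing; all other
chamber vertices are bitwise identical across composites built from one
template.

## Geometric descriptors

- V: enclosed volume of the rim-capped appendage (divergence theorem).
- A_s: lateral surface area (the ostium is an aperture, not wall).
- A_o, P_o: area of the rim polygon projected to its least-squares plane
  (shoelace) and the polygon perimeter. The projection is the chosen
  reading of "orifice area" (vs a minimal spanning surface); a
  self-intersecting projection falls back to the barycentric fan area.
- L, chi: from the centerline.

**Centerline.** A marching tracer starts at the ostium-rim barycenter,
heading along the inward rim normal, and advances in steps of 0.4× the
local wall clearance; each new point is relaxed onto the medial axis in
the plane perpendicular to the heading (move away from the nearest wall
sample). The march stops at the distal cap (wall directly ahead within one
clearance, abrupt clearance drop, or heading reversal) and the polyline is
closed on the wall along the local tangent, lightly smoothed, and measured.
On the generator's oracles this gives chi < 0.02 for a straight duct and
chi within 10% of π/2 − 1 for a semicircular one; mid-range tortuosities
are reproduced with a mild low bias (smoothing shortens L slightly), which
is acceptable because the study-set classes are separated by construction.

## Flow model

Blood: incompressible Newtonian, density 1.06 g/cm³, dynamic viscosity
0.035 poise. Arbitrary Lagrangian–Eulerian convection: the convective
velocity is fluid velocity minus mesh velocity.

**Boundary program (AF).**

- MV flowrate Q^O(t): zero during the systolic fraction (0.35 T), then a
  half-sinusoid E-wave over 0.45 T, no A-wave (atrial contraction is
  absent in AF). Defaults: period T = 0.8 s (75 bpm), peak 250 ml/s →
  stroke volume ≈ 57 ml (≈ 4.3 l/min, a plausibly reduced AF output). The
  source waveform's numbers are not published; everything is configurable.
- PV inflows: mass balance Σ_l Q_l^pv + Q^O + dV/dt = 0 split by PV
  sectional area. Because PV sections move with the wall, the wall-motion
  flux Q_l^w of each section is subtracted from its prescribed relative
  flux; the *absolute* section fluxes (prescribed + wall) close the
  balance to machine precision. Inlet profiles are plug by default
  (parabolic available), rescaled so the *discrete* patch flux is exact.
- MV outlet: traction-free natural condition plus backflow penalization
  −β ρ min(u·n, 0) u with β = 0.2 (a common value for this penalization).
- Wall motion: d_v(t) = a r_v sin(2π f t) n_v with amplitude a = 0.1 mm,
  f = 4 Hz, r_v ~ Uniform(0,1) i.i.d. per vertex (seeded). The interior
  mesh-motion field is the harmonic extension of the boundary values,
  solved once; since the amplitude is far below the cell size the FE
  operators are kept on the reference mesh (quasi-static small-displacement
  ALE) and the motion enters through the mesh velocity, the boundary
  fluxes and dV/dt.

**Discretization.** P1 tetrahedra; incremental pressure projection:
(1) tentative momentum with implicit diffusion, semi-implicit (Picard)
convection, streamline-upwind stabilization (transient tau), the old
pressure gradient and Dirichlet inlet/wall values; (2) pressure-increment
Poisson with phi = 0 at the MV; (3) lumped-mass projection, iterated 3×
because a single lumped sweep only damps the discrete divergence.
Because the pressure test space excludes the outlet, the divergence of
outlet-adjacent cells is uncontrolled and the raw outflow lags the
waveform by O(h); an outlet compatibility correction (a uniform normal
velocity on the free MV nodes) closes the global balance exactly at every
step. Its magnitude is recorded in the result series (`outlet_correction`;
at desk resolution it stays below ~10% of the peak flowrate). Momentum
systems are re-factorized each step (SuperLU, MMD ordering); runs are
bitwise deterministic for a fixed seed and mesh on one thread.

**Verification.** Steady flow in a straight tube (Re ≈ 30) reproduces the
analytic Poiseuille centerline velocity within 5% at ≈ 2.5·10⁴ tets;
unforced flow with backflow penalization dissipates kinetic energy
monotonically; halving dt changes the steady solution by < 10%.

**Volume meshing.** Constrained-by-filtering Delaunay: surface vertices
plus supplementary on-surface samples (so flat port caps do not sag) plus
an interior lattice, keeping tetrahedra whose centroid lies inside.
Boundary faces inherit the label of the closest surface point, with a
normal-agreement guard so stair-step faces near port rims fall back to the
wall. The appendage lumen is refined by a finer lattice inside the closed
appendage surface; without it a ~0.5 cm-radius tube vanishes from a
0.4 cm background mesh.

## Stasis metrics

- **Q-criterion** per cell from the exact P1 velocity gradient. The
  *printed* convention uses S and W without ½ factors, so solid-body
  rotation at rate ω gives Q = 4ω²; the *standard* convention gives ω².
  Vortex regions are face-connected components of {Q > 0}.
- **Ostium velocity**: area-weighted mean of u·n over a disc spanning the
  grafted rim, oriented so emptying is positive; a peak below 20 cm/s
  flags poor washout. Note that for a blind pouch with nearly rigid walls
  the *net* normal flux is intrinsically small; this trace reflects net
  filling/emptying, not the much larger in-plane swirl.
- **Particles**: 500 passive tracers seeded uniformly in the largest ball
  centred at the centerline midpoint (radius capped at 0.8× local
  clearance), advected by RK4 with linear interpolation in space and time.
  Wall encounters snap the particle back toward the nearest cell; exits
  through the MV freeze it as departed. Residence at the end of cycles 3,
  4 and 5 is instantaneous membership in the closed appendage region
  (particles may re-enter; a `first_exit` mode is available), and the
  residual fraction is 100·count/n₀ to one decimal.

## Resolution tiers and problem sizes

| tier | background cell | appendage cell | cycles | typical tets |
|------|-----------------|----------------|--------|--------------|
| test | 0.55 cm | 0.26 cm | 2 | ~1.5·10⁴ |
| desk | 0.40 cm | 0.21 cm | 5 | ~2.8·10⁴ |
| full | 0.25 cm | 0.14 cm | 5 | ~10⁵ |

`desk` is the tier used for the reported experiments: it resolves the PV
jets and the appendage lumen with 4–5 cells across while keeping a
two-model, multi-seed study tractable on a single CPU core. `full` is
defined but not exercised by the shipped tests.

## What the synthetic experiments do and do not show

The generator reproduces the *geometric* conditions of the study
population (appendage volume, length, tortuosity, orifice calibre ranges)
on an idealized smooth chamber. Passing tests demonstrate that the
pipeline's machinery is correct (oracle-verified geometry, conservative
boundary program, verified solver, exact bookkeeping) and that the
directional effect — a long tortuous appendage washes out more slowly
than a short straight one on the same chamber — emerges robustly across
seeds. They do not demonstrate patient-specific accuracy: the chamber has
no trabeculation or pectinate muscles, wall motion is a stochastic
surrogate, the desk-scale mesh damps fine-scale swirl (absolute washout
is slower than in high-resolution patient models), and reported absolute
velocities and residual fractions should be read as order-of-magnitude,
not clinical, values.

## Known limitations

- The Delaunay-filter mesher recovers boundaries to one cell size; it is
  not a quality-guaranteed tetrahedralizer.
- Mid-range tortuosity is slightly underestimated by the centerline
  smoothing; class membership (simple vs complex) is unaffected.
- The projection solver targets desk-scale meshes; it re-factorizes each
  step and would need an iterative solver beyond ~10⁵ cells.
- Particle advection treats walls by snap-back rather than exact
  reflection; with the 4 Hz vibration amplitudes used, wall encounters
  are rare.
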