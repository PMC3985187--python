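# Methods

`pavemech` models the mechanics of the outer epidermal wall of plant
pavement cells and the image/force-curve/event analyses used to read
out the cytoskeletal response. Everything runs on synthetic inputs with
known ground truth; this note records the models, their assumptions,
the default parameters, and the design choices where the design was
genuinely open.

Unit system throughout: micrometre, MPa, minute; forces come out in
microNewton (MPa·µm²). AFM curves use nm and nN with one explicit
conversion constant (MPa·nm² = 10⁻³ nN).

## Wall mechanics

**Model.** The outer (periclinal) wall is a thin hyperelastic membrane
under turgor. Constant-strain triangles in a total-Lagrangian setting:
per element the tangent-plane deformation gradient **F** (3×2) gives the
Green–Lagrange strain **E** = ½(**F**ᵀ**F** − **I**). The energy density
is Saint Venant–Kirchhoff plus a quadratic transversely isotropic fiber
invariant,

    W(E) = ½ λ tr(E)² + μ tr(E²) + ½ ζ (aᵀE a)²,

with plane-stress Lamé constants λ = Eν/(1−ν²), μ = E/2(1+ν) so that a
uniaxial stress test of the membrane has stiffness exactly `E_matrix`.
The unit vector **a** is the cellulose-microfibril direction in the
element plane; ζ is calibrated so the constrained-axial small-strain
stiffness along the fiber, ∂²W/∂ε_aa² = λ + 2μ + ζ, equals
`fiber_ratio` times the matrix value λ + 2μ. Anticlinal walls enter as
axial bars (Green strain) along the cell-boundary polylines with the
matrix modulus, thickness one fifth of the wall, and cross-section
area = beam thickness × wall thickness (the in-depth extent of the
anticlinal wall is not modelled; this area choice makes the beam
stiffness scale with both knobs and is configurable through them).

**Defaults** (all configurable on `MaterialParams`): matrix modulus
40 MPa, fiber ratio 5, turgor 0.2 MPa, wall thickness 1 µm, beam
fraction 1/5, outer-boundary expansion 1% — the wall-mechanics
parameter set the model family is normally run with. The matrix
Poisson ratio is not part of that set; we default to ν = 0.3 because
plane-stress SVK degenerates at 0.5 (0.5 is used only in the AFM
contact models, where incompressibility is the convention).

**Loads and constraints.** Turgor is a follower pressure (normal to the
deformed surface, per cell) with its exact — unsymmetric — load
stiffness assembled. Tissue tension enters as a prescribed radial
expansion of the outer template boundary about the template centroid.
Every vertex on a cell-boundary polyline is restricted in z (it keeps
its initial height); the outer boundary is additionally prescribed in
the plane. Pure membranes have no transverse stiffness at a flat,
unstressed start, so the Newton iteration matrix carries a tiny
adaptive diagonal shift (10⁻⁸·E·t, scaled by the residual); this
perturbs only the iteration path, never the converged solution, and
no bending term is needed for the load cases shipped here.

**Solver.** Newton–Raphson on the residual (internal force minus
follower pressure), incremental loading (default 3–4 increments),
backtracking line search on the residual norm, sparse LU for the
unsymmetric tangent. Convergence at relative residual 10⁻⁸ (plus
10⁻¹⁰ absolute), `max_iter` 200. These numerical settings are ours;
the model family they implement prescribes none.

**Stress readout.** Cauchy membrane stress = 2nd Piola–Kirchhoff
pushed forward and divided by the in-plane area change (thickness
taken as unchanged; strains here are a few percent), then
eigen-decomposed in the deformed tangent plane into σ1 ≥ σ2 with
orthogonal unit directions. Elements with σ1−σ2 < 10⁻⁶·|σ1| are
flagged degenerate; their direction is reported but not trusted, and
the feedback loop keeps the previous fiber there to avoid noise-driven
flips.

**Verification.** The element force is checked against finite
differences of the energy on every test run; a pressurized sphere
(R = 20 µm, t = 1 µm, P = 0.2 MPa) reproduces PR/2t = 2 MPa within
5%, and a capped cylinder gives hoop:axial = 2.00. Mesh-refinement
error is measured against the deformed-configuration closed form
P·R_def/2t: inflation strain is ~3.5% here, so the stress converges to
2.07 MPa, and only the comparison against the deformed radius isolates
the discretization error (4.5% → 1.1% → 0.3% over three octahedron
subdivision levels — second order).

## Feedback between stress and fiber direction

Starting from the isotropic (fiber-free) solution, the loop
re-solves with the anisotropy axis set per element to the previous
step's σ1 direction (pulled back to the reference frame through
**F**), until the median fiber rotation per step falls below 1° (cap
15 steps; a non-decreasing rotation over five steps is treated as
oscillation and the best iterate is returned with a warning). The
reported observable is the per-element |cos| between the isotropic and
feedback σ1 directions. On lobed templates the median is ≈ 0.98:
geometry, not material anisotropy, sets the stress pattern.

## Synthetic tissue geometry

Jigsaw templates are bounded Voronoi partitions (mirrored seeds;
vertices snapped to a 0.0025·domain grid to collapse the micro-edges
near-cocircular seeds create) whose interior walls receive a
sinusoidal displacement: amplitude 2 µm, wavelength 8 µm by default,
with a sin(πs/L) envelope so walls stay anchored at junctions. Each
displaced wall is a single shared polyline, so area moves only between
neighbors and the template area is conserved exactly. If a modulated
template self-intersects, the amplitude is damped ×0.7 and the
modulation retried (logged). The generator also emits ground-truth
neck/lobe landmarks — the modulation extrema with the inward normal
and the indented cell — which the stress analyses score against.
There are no published lobe-geometry statistics to fit; amplitude and
wavelength are free knobs chosen once to give clearly indented,
non-self-intersecting cells at the 20 µm cell scale.

Meshing is boundary-conforming by construction: every wall polyline is
resampled at the target element size and appears as element edges;
interiors are filled with a hexagonal lattice (spacing 0.92·h,
clearance 0.42·h — chosen so all element edges stay below 1.5·h),
triangulated with Delaunay, filtered by centroid containment, and
Laplacian-smoothed. Degenerate slivers from collinear boundary samples
are dropped.

## Perturbations

**Ablation/laceration** removes turgor from the cut cells and softens
their membrane and interior beams by `stiffness_factor` (default 0.1 —
the wound must become mechanically passive but keep the tangent
well-conditioned; the model family states only "reduction of wall
elasticity"). Wound-margin beams shared with a survivor keep the
survivor's wall. The outcome metric, `circumferential_alignment`, is
the area-weighted mean cos² between σ1 and the local wound tangent
over an annulus (default one cell diameter); 1 = circumferential,
0 = radial, 0.5 = random. The wound outline is morphologically closed
(4 µm radius) before scoring so the tangent follows the wound rather
than each lobe of the dead cells' jigsaw margins.

The large-cut vs single-cell comparison uses a compact multi-cell
wound at the center of a 36-cell, 120 µm template. Slit-shaped cuts
are a poor desk-scale emulation: their tips and the clamped template
frame dominate a one-cell-diameter annulus and can score below a
single-cell wound, whereas the experimental laceration is vastly
larger than any cell. With the compact wound the ordering laceration >
single cell > baseline is robust across template seeds.

**Compression** presses a rigid frictionless plane (penalty on vertex
penetration, z-forces only) onto a pressurized spherical cap while a
secant iteration rescales the internal pressure until the enclosed
volume (z-flux integral against the fixed base plane) returns to its
unconfined value within 0.5%. Stress off the contact patch rises
monotonically as the gap closes.

**Elevated stoma.** The guard-cell dome is a Gaussian bump
(σ = radius, unclipped) on a flat sheet; the guard-cell ring sits
elevated on the flank and the topography decays smoothly into the
sheet. Under the standard loading (all cells pressurized, 1% tissue
tension, z-restricted cell boundaries) σ1 around a tall bump
(height ≈ radius) is strongly circumferential (score ≈ 0.95), and the
pattern vanishes for a flat stoma — the elevation contrast is the
physics, not a parameter choice: with little elevation the pressurized
cap's meridional pull on its ring wins and the near field is radial.

## Filament images and the nematic score

Filaments are analytic Gaussian ridges (continuous sub-pixel position
and orientation) drawn as full image chords and summed — overlap means
bundling, not saturation, and the texture has no rasterization
anisotropy. Orientations are mean + ½·wrapped-normal noise with
σ = √(−2 ln S), which gives the target 2D nematic order parameter
S = |⟨e^{2iθ}⟩| exactly in expectation (S = 1 ⇒ all angles equal;
S = 0 ⇒ uniform). Additive Gaussian pixel noise and 8/16-bit
quantization are optional. The generator does not emulate confocal
photophysics, out-of-focus background, or curved-surface projection;
image-analysis results on it validate the estimator, not microscope
robustness.

The anisotropy estimator averages the gradient structure tensor
(Gaussian derivatives, σ = 1.5 px, mirror padding — constant padding
fabricates axis-aligned border edges) over the ROI and rotates it 90°
(filaments run perpendicular to the gradient). Scores are
score_v1 = (λ1−λ2)/(λ1+λ2) ∈ [0,1] and score_v2 = 2·score_v1 ∈ [0,2];
the 0–2 variant is the eigenvalue difference of the traceless nematic
tensor Q = 2T − I over tr T = 1, which reconciles the printed
difference-over-trace formula with both printed bounds. Averaging the
tensor itself (energy weighting) rather than unit orientation vectors
matters: the unit-vector form normalizes per pixel and amplifies
sampling imbalance roughly threefold, while the tensor average tracks
the ground-truth order parameter to ~0.005 across S ∈ [0, 1]. ROIs are
polygons in pixel coordinates; an inward offset (default 3 px) removes
the anticlinal-wall band when requested. Flat ROIs are flagged
degenerate and score 0.

## AFM force curves

Forward models: Sneddon cone F = (2/π)tan α · E/(1−ν²) · δ² on
approach, and DMT sphere F = (4/3)E*√R(d−d₀)^{3/2} − F_adh on retract
(zero out of contact), with reduced modulus E* = E/(1−ν²) and the
apparent modulus reported as Ea = E*(1−ν²). Defaults: half-angle 18°,
R = 6 nm (middle of the manufacturer range), ν = 0.5.

Fitting detects the contact point with a piecewise model (flat zero
baseline + power law): coarse scan over sample positions, continuous
bounded refinement. For DMT, F_adh starts at −min(retract) and is then
refined by joint least squares with the contact law inside the
contact-point search, because the raw minimum is quantized to the
separation sampling (2.5% at the default grid). Both fits invert their
own forward models exactly at zero noise, with <2% bias at 5%
multiplicative noise. Grids whose curves share a separation axis are
fitted in one vectorized pass (batched scan + parabolic refinement),
which is what makes 128×128 maps cheap; the per-curve path is the
reference implementation. No substrate/finite-thickness correction and
no cantilever calibration are modelled.

## Severing and statistics

Severing events are homogeneous Poisson in space and time; rates are
per-cell counts/(area·time), summarized as mean ± SD across cells
(severing convention) while anisotropy summaries use mean ± SE.
Crossover densities are normalized per 10 µm² and percent change is
computed on group means, rounded to the nearest integer. Group
comparisons: two-sided Mann–Whitney U (exact when the pooled sample is
≤ 20 without ties, tie-corrected normal approximation otherwise) or
Student's t.

## Problem sizes

The shipped analyses and tests use 12-cell/60 µm templates (~2.8 k
elements) for pattern and feedback runs, a 36-cell/120 µm template
(~5.7 k elements) for the wounding comparison, octahedron-subdivision
spheres at 128–2048 elements for the Laplace oracles, and 16×16 to
128×128 AFM grids. These sizes resolve lobes with ~4 elements per
wavelength and leave all reported quantities mesh-converged at the
tolerance of their checks.

## Known limitations

- Membrane-only kinematics: no bending stiffness, so wrinkling under
  strong compression is not represented; the compression study stays in
  the mildly flattened regime.
- The anticlinal/inner walls are beams + z-restrictions, not a 3D
  solid; large turgor destabilizes the in-plane boundary equilibrium,
  so the default pressure stays at 0.2 MPa.
- Passing image tests on ridge textures shows estimator correctness,
  not robustness to real confocal artifacts (background, bleed-through,
  drift).
- The severing generator is spatially homogeneous per cell; it cannot
  test detectors of spatial clustering.
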