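# Methods

## Physical model

EMDA treatment is a quasi-static DC problem: a controlled current
(default I = 20 mA) flows from a helical silver electrode inside the
saline-filled bladder to two dispersive skin patches on the lower
abdomen.  At DC the body is a volume conductor; the potential obeys

    div( sigma grad V ) = 0

with no-flux (insulating) conditions on the body surface and on internal
insulators, and equipotential electrode surfaces constrained by the total
injected current rather than a fixed voltage.  Tissue conductivities are
piecewise constant per segmented class (S/m): bladder wall 0.2, bladder
lumen (saline) 1.5, prostate 0.41, fat 0.012, muscle 0.2, intestines 0.4,
bone 0.02.  The catheter balloon, any internal air, and the exterior are
perfect insulators and are removed from the computational domain rather
than given a small conductivity — this matches the physics and avoids
ill-conditioning.

The quantities of interest are the electric field magnitude |E| (drives
membrane charging, hence electroporation) and the current density
magnitude |J| = sigma |E| (drives iontophoretic transport).

## Synthetic anatomy

No patient segmentation ships with the package, so a parametric phantom
emulates one.  All primitives are analytic (ellipsoids, spheres,
cylinders) so region volumes have closed forms the tests can check:

| structure | default geometry |
|---|---|
| body | ellipsoid, half-axes 125 / 90 / 140 mm, truncated to ±90 mm axially (a CT stack covers a finite z range) |
| subcutaneous fat | outer 12 mm shell of the body ellipsoid |
| bone | posterior spine cylinder (r = 18 mm) + two lateral cylinders (r = 12 mm) |
| intestines | ellipsoid above the bladder, half-axes 70 / 52 / 45 mm |
| bladder | spherical shell, outer radius 35 mm, wall 3 mm, center (0, 25, 0) mm |
| air pocket | topmost 5 % of the lumen volume, cut by a horizontal plane (buoyancy) |
| prostate | 20 mm sphere tangent below the bladder |
| balloon | 12 mm insulating sphere abutting the inferior lumen (bladder neck) |
| helix | 0.4 mm wire, 20 turns, major radius 1.25 mm, pitch 1.6 mm → 32 mm long, axis vertical through the lumen center |
| patches | two 5 × 7 cm rectangles projected onto the anterior skin at x = ±45 mm |

Dimensions are ordinary adult-pelvis values; electrode geometry and the
conductivity table follow the clinical EMDA hardware and the tissue
dielectric literature.  The exact intravesical electrode position during
a real treatment is unknown even in principle (it floats with the
catheter), so "helix centered in the lumen, axis vertical" is a
documented package choice, and `PhantomParams.seed != 0` applies a ≤ 5 %
jitter to organ centers/radii for sensitivity studies (seed 0 = the
canonical anatomy, bit-reproducible).

What the phantom does *not* emulate: true CT anatomy (organ shapes,
contact topology, anisotropy), bladder filling variation, urine/saline
mixing, and the skin as a distinct tissue layer (skin enters only as the
electrode contact layer, below).  Consequently, tests passing on the
phantom show the *method* behaves correctly (conservation, convergence,
qualitative field structure, mechanism regime); they do not certify
patient-specific field values, which is why desk-scale numbers here are
compared only against regime bounds (e.g. peak bladder-wall |E| well
below 100 V/m), not against any patient-specific result.

## Discretization and solver

* **Scheme** — 7-point finite volumes on the label grid.  The face
  conductance between voxels a, b is `(A/h) * 2*sa*sb/(sa+sb)` (harmonic
  mean × face area / center distance): exact for series composition of
  piecewise-constant sigma and discretely conservative.  Faces touching
  excluded voxels carry zero conductance.  A voxel scheme was chosen over
  a body-fitted FEM mesh because the inputs are voxel segmentations; on
  them the assembly is exact and the whole solver stays ~200 lines of
  sparse linear algebra.
* **Terminals** — all voxels of one electrode group collapse into a
  single equipotential node.  Electrode metal voxels carry a silver-like
  sigma, which makes the half-cell face conductance toward tissue
  `2*sigma_tissue*A/h`; with plate electrodes this reproduces Ohm's law
  for a slab *exactly* (the tests assert this to 1e-6).
* **Current source** — solve once with Dirichlet values 1 V / 0 V on the
  two groups, measure the resulting terminal current I₁ by summing face
  currents around the source node, then scale V, E, J by I/I₁.  For a
  linear two-terminal problem this is identical to a constrained
  current-source solve but keeps the system symmetric positive definite.
* **Skin contact layer** — a thin resistive layer on the patch–tissue
  faces only, as a per-area conductance g in series with the face
  conductance.  Default g = 2 S/m² (≈ 0.5 mm of 0.001 S/m dry skin).
  This value is a package default, not a literature constant: it shifts
  the terminal voltage at fixed current but — by the linear rescaling —
  cannot change interior fields, which is why the dosimetry results are
  insensitive to it.  (For the same reason the simulated terminal voltage,
  3.1 V on the default phantom, is the least transferable output: it
  depends on contact impedance and anatomy details that the phantom does
  not attempt to match.)
* **Linear solve** — conjugate gradients with Jacobi preconditioning,
  zero initial guess (bit-stable reruns), relative residual 1e-8,
  iteration cap 1000·N^(1/3).  The default phantom (≈ 0.69 M unknowns,
  conductivity contrast 125:1) converges in ≈ 600 iterations / ≈ 10 s on
  one CPU.  Disconnected conductive islands are dropped from the unknown
  set (their potential is undefined); disconnected *terminals* raise a
  topology error.
* **Fields** — E = −∇V by central differences, falling back to one-sided
  differences at domain boundaries and next to excluded or terminal
  voxels.  Using one-sided stencils at terminal-adjacent voxels (rather
  than differencing across the equipotential node) makes a uniform slab
  field exact everywhere it is defined.  E and J are reported as NaN
  inside terminals and insulators.

### Grid resolution

The default spacing is 2 mm: the full pipeline (generate + solve +
report) then runs in seconds-to-a-minute on a laptop CPU while the
voxelized organ volumes are within a few percent of their analytic
values, and the analytic-oracle tests show ≤ 2 % field error away from
electrode singularities at 1 mm.  Finer grids are supported (1 mm is used
in the oracle and volume-convergence tests); spacing coarser than 2 mm
raises a resolution error for the helix, whose whole envelope is only
~2.9 mm across.  The helical wire (0.4 mm) is itself thinner than any
practical voxel: the voxelizer therefore stamps every voxel the
centerline passes through in addition to the swept-tube membership test,
guaranteeing a 26-connected conductor.  Because the wire voxels are
terminal constraint nodes (not interior unknowns), their inflated
cross-section perturbs only the near-field within a voxel or two of the
electrode, not the bladder-wall dosimetry.

## Dosimetry conventions

* Statistics are computed over the non-excluded, non-terminal voxels of
  one label; SD is the population form (divide by n).  The choice is
  recorded here because mean/SD pairs are convention-sensitive.
* The raw maximum is reported together with its voxel location and with
  a top-0.1 %-winsorized maximum: in voxelized solves the global extremum
  often rests on one voxel at a material corner and must be auditable as
  a possible discretization artifact.
* The anterior/posterior split plane is the y-midplane of the label's
  bounding box; the asymmetry direction follows the patch placement (and
  reverses when the patches are moved to the posterior skin — a property
  the test suite checks by simulation).

## Mechanism assessment

* ITV uses the steady-state spherical Schwan form, ITV_max = 1.5·E·R,
  with no membrane-conductance or frequency correction — appropriate for
  DC exposure, and conservative (an upper bound at the cell pole).
  Urothelial superficial cells are polyhedral, not spherical; the
  spherical formula with R = 125 µm (half the 250 µm maximal diameter) is
  used as the standard first-order estimate.
* Electroporation thresholds: 40 000 V/m (conventional pulses) and
  10 000 V/m (the lowest literature value, for 100 ms exposures).  The
  verdict `electroporation_excluded` requires a strictly zero fraction of
  voxels above *both* thresholds.
* The iontophoresis window 1–5 A/m² (0.1–0.5 mA/cm²; the conversion
  factor is exactly 10) is treated as a closed interval.
* On the default phantom at 20 mA every tissue is orders of magnitude
  below both electroporation thresholds (peak bladder-wall ITV ≈ 4 mV),
  while ~half of the bladder-wall voxels lie inside the iontophoresis
  window — the regime consistent with iontophoretic drug transport.

## Degenerate inputs and tie-breaks

* `turns = 0` helix → empty mask; an empty electrode at solve time is an
  error.
* A patch rectangle with no body underneath → empty mask + warning from
  the voxelizer, placement error from the phantom generator.
* `air_pocket_fraction = 0` → no air label at all.  The air cut plane is
  a z-quantile of lumen voxel centers; boundary voxels exactly on the cut
  stay saline.
* Labels present in a volume but absent from the conductivity table raise
  a configuration error naming the label; unknown YAML keys are rejected
  rather than ignored.

## Known limitations

* Static solve only: the clinical generator ramps the current at 50 mA/s
  and holds for 30 min; by linearity the static solution at the plateau
  current describes the whole treatment up to that ramp, but no
  time-dependence (heating, electrochemistry, drug transport) is
  modelled.
* Conductivities are isotropic and frequency-independent; no tissue
  anisotropy (muscle fiber direction) is represented.
* Drug (mitomycin C) transport itself is out of scope — the package
  characterizes the electrical exposure, not the resulting concentration
  profile.
* The phantom is one parametric anatomy, not a population; inter-patient
  variability can be explored only coarsely via the jitter seed.
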