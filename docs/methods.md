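# Methods

`fangmech` re-implements, as a tested pipeline, a microCT-based analysis of
venomous snake fangs: 3D morphometrics of the three venom-delivery
phenotypes, voxel-based static load simulation with Von Mises stress
statistics, and compression-test analysis connecting the structural modulus
to a material modulus through cellular-solid scaling.  Because the original
scan deposit is large and external, a parametric synthetic-fang generator
with exact ground truth stands in for scan data throughout the test suite;
the same pipeline runs unchanged on TIFF image stacks or STL surfaces of
real scans.

## Coordinate and unit conventions

All lengths are micrometres, moduli and stresses pascal, forces newton.
Voxel grids are isotropic, 0-based, with the physical position of voxel
`(i,j,k)` at `origin + (i,j,k)·voxel_size` (voxel-centre convention,
right-handed axes).  Binary volumes carry labels {0 = background,
1 = material}.  The FEM solve converts to SI metres internally and reports
displacements back in micrometres.

## Synthetic fang generator

A fang is a tapered circular cross-section swept along a circular arc of
radius `arc_radius` spanning `segment_angle` degrees; the outer radius
varies linearly with arc length from `base_outer_radius` to
`tip_outer_radius` (fangs are cone-like; linear taper is the simplest shape
consistent with that).  Internal anatomy:

* **Venom canal** — radius `canal_radius_fraction × local outer radius`,
  centre offset toward the concave (inner-curve) side by 15% of the local
  clearance.  It runs the full length and exits through a carved orifice on
  the concave wall at `orifice_arc_fraction` (default 0.1) of the arc from
  the tip, closing smoothly beyond the orifice so the tip is solid.
* **Pulp cavity** — a second cavity in the basal 40% of the arc, offset
  toward the convex side, tapering linearly to zero.
* **Phenotype**: `open_groove` removes a wedge (`groove_open_angle`,
  default ~50°) from the canal roof through the concave wall, leaving an
  open channel; `closed_nonfused` cuts a thin suture notch
  (`suture_depth_fraction` of the local wall, width 8% of the outer radius)
  into the concave surface; `closed_fused` leaves the wall intact.

Generation is deterministic given the parameters.  A `ResolutionError` is
raised when the thinnest canal wall would span fewer than 2 voxels.
Landmarks returned with each volume — tip, orifice, base plane, a 21-point
centreline polyline, and the curvature-plane normal — are exact, so
parameter-recovery tests measure only the pipeline's own error.  The
centreline stands in for the manually digitised top-of-fang polyline of a
real workflow; its arc length equals `arc_radius · segment_angle` exactly.

**Presets.** Two presets per phenotype encode the qualitative contrasts
reported for real fang types: closed-fused fangs are the most curved
(segment angles 146–156° vs 102–112° nonfused vs 65–78° open groove), the
most slender and the relatively longest; open-groove fangs have the
smallest canal fraction and hence the thickest size-corrected walls and the
highest material volume fraction (≈0.77 vs ≈0.75 vs ≈0.70 at the
mid-section).  Absolute dimensions (arc lengths 4.5–7.7 mm, mid-fang
diameters 1.0–1.6 mm, skull lengths 23–30 mm) are plausible for
medium-sized snakes; no published numeric ranges exist for cavity radii or
suture depth, so only the orderings — not absolute values — should be read
as biological.

**Ground-truth cross-section reference.** `reference_section_metrics`
rasterises the analytic cross-section at any arc position on a fine 2D grid
(1200² by default) and reports the true BV/TV (against the full outer disc
as envelope) and mean wall thickness (2D local thickness).  Recovery tests
compare the 3D pipeline against this reference, isolating discretisation
and algorithmic error from geometric truth.

**Compression records.** `generate_compression_record` emulates a
dried-fang compression curve: a strictly linear ramp of structural
stiffness `E_eff·A/L` up to 95% of the yield plateau, an exponential
roll-over (value- and slope-continuous) to the plateau at
`yield_stress·area`, and a linear post-yield drop from 1.5× the yield
strain.  Gaussian noise of configurable standard deviation is added to the
load channel; the record is reproducible for a fixed seed.  The sharp knee
(5% roll-over amplitude) makes the 0.2%-offset yield of the noiseless curve
agree with the nominal yield stress to ~1%.

## Morphometrics

The five statistics and their estimators:

* **Fang length** — polyline arc length (≥10 points, base→tip).
* **Relative fang length** — fang length / skull length (skull length is
  scalar metadata).
* **Curvature** — a circle is fitted to the polyline: total-least-squares
  plane projection, algebraic (Kåsa) fit, geometric Levenberg–Marquardt
  refinement.  The segment angle accumulates the wrapped angle increments
  of consecutive points about the fitted centre, so arcs beyond 180° are
  representable (an end-to-end chord angle would alias them).  Collinear
  input raises `CollinearPointsError` rather than returning a huge radius.
* **Mid-fang diameter** — material voxels in a one-voxel slab normal to the
  polyline at its arc-length midpoint are projected into the section plane;
  the outermost point per angular bin (72 bins) forms the outer outline,
  ignoring cavities and a groove opening, and the same circle fitter
  returns the diameter.  One voxel is added to compensate the half-voxel
  inward bias of outermost voxel *centres* relative to the true surface.
* **Mid-section ROI** — all material voxels whose arc-length projection
  onto the polyline lies within ±5% of total length around the midpoint
  (10% window).  The frame also carries an axially extended copy (+5% per
  side): envelope statistics are computed there and counted in the core
  window only, because the venom canal crossing the slab's cut faces would
  otherwise leave ball-lid recesses in the closed envelope (measured bias
  up to +0.07 BV/TV on open-groove geometry without the extension).
* **BV/TV** — BV is the material voxel count; TV is the volume inside the
  closed outer envelope: morphological closing with a Euclidean ball of
  radius 1.5× the maximum local wall thickness (sealing the groove and
  suture openings; the factor is configurable), then hole filling.
  Closing is computed by distance transforms, so large radii are exact and
  cheap.  The closing lid is slightly recessed where it seals a wide
  opening (ball sagitta), so TV under-counts by a few percent for extreme
  openings; at the presets' groove widths the net BV/TV error stays below
  0.05.
* **Wall thickness** — the local-thickness definition standard in
  trabecular-bone microCT: for each material voxel, the diameter of the
  largest sphere fully inside the material containing it, computed by a
  descending-radius sweep over the Euclidean distance transform (radius
  step 0.5 voxel, capped at ~40 sweeps for large structures).  The mean is
  taken over the full 10% ROI rather than a single slice (both are
  defensible readings of "the middle of the fang"; the region average is
  the more stable estimator), evaluated on the extended ROI so inscribed
  spheres are not clipped by the cut faces.

All measurements are invariant under rigid motion of the volume up to
discretisation (1–2 voxels).

## Voxel-based load simulation

Each material voxel becomes one 8-node hexahedral element with trilinear
displacement interpolation; the isotropic elastic element stiffness
(E = 20 GPa, ν = 0.3 by default — literature indentation values for fang
material) is integrated with 2×2×2 Gauss quadrature and
assembled sparsely.  No surface meshing, smoothing or element erosion is
applied; jagged voxel surfaces are accepted and their stress hotspots are
absorbed by the summary statistic (below).

**Boundary conditions.** Two regions of interest: the *fixed* region (all
material voxels within 3 voxel layers of the base plane; every displacement
component of their nodes is zero) and the *load* region (material voxels
within half the tip-to-orifice distance of the tip point).  The tip axis is
the unit vector from orifice to tip.  The load (5 N nominal) is distributed
equally over the exposed surface nodes of the load region; an area-weighted
face-traction alternative (`load_application="face"`) exists and is used by
the analytic oracle tests, where a uniform end traction is the reference.
The parallel case loads along −tip_axis (compressing the tip); the lateral
case loads along the curvature-plane normal, i.e. at 90° out of the fang's
curvature plane.  (The in-plane perpendicular is the other defensible
reading of "lateral"; measured on the presets it gives systematically
smaller ratios, 1.3–2.8 vs 1.8–2.9.)

**Solver.** Conjugate gradients with Jacobi preconditioning, relative
tolerance 1e-8, iteration cap 2000, or a sparse LU direct solve; `method="auto"` picks the
direct solver below 250k free DOFs.  Diagnostics record iterations,
residual, and the reaction-force sum (global force balance is checked in
tests to 1e-3 of the applied load).  An optional majority-rule downsampling
(`coarsen`, mirroring a simulation cell size larger than the scan voxel) is
available for large scans.

**Stress recovery.** Strain at the element centroid (single recovery
point), stress by the constitutive matrix, Von Mises from the full tensor.
The summary statistic is the mean of the top decile of per-element Von
Mises values (ties at the threshold included, fractional count rounded up):
a hotspot-insensitive measure of the bulk stress level, configurable via
`percentile`.  The raw maximum is also recorded.  On the presets the
statistic changes by <10% when the voxel resolution doubles, which is the
justification for reading it as a morphology property rather than a mesh
artefact.

**Effective structural modulus.** For an axial load,
`E_eff = (F/A_env)/(δ/L)` with δ the mean displacement of the loaded nodes
along the load direction, `A_env` the outer-envelope cross-section area at
mid-fang and L the fang length.  On a solid prism this recovers the
material modulus within 3% (the fixed element layer and the clamped-base
Poisson constraint account for most of the residual); on a hollow prism it
scales with the material fraction.

## Compression-test analysis

Engineering stress = load / cross-section area at the failure location;
engineering strain = displacement / total fang length (both single scalars,
hence *engineering* rather than true measures).  The default area is the
outer-envelope area, consistent with a structure-level modulus that
includes the cavities.

* **Linear modulus** — local slopes by Savitzky–Golay differentiation
  (window ≈ n/10, quadratic); the linear region is the longest contiguous
  pre-peak run whose slope stays within 10% of the run's median, found by
  seeding the reference slope from several percentiles and refining
  (a single seed can lock onto the roll-over shoulder on noisy data).  The
  least-squares slope over the window is reported.
* **Yield** — 0.2% strain-offset convention against the fitted line
  (intercept included, so a toe region does not shift the offset line).
  The intersection is sought on a smoothed copy of the curve, beyond the
  linear window (both guards suppress single-sample noise crossings).  If
  no intersection exists before the stress maximum, the maximum is
  returned and flagged.
* **Straight-rod reference stress** — `σ = F/(π r² · BV/TV)` at the
  mid-fang radius: what the same force would produce in a material-fraction-
  corrected straight rod, neglecting curvature and taper.
* **Foam scaling** — Gibson–Ashby open-cell relation
  `E_eff/E_s = (BV/TV)²`; exponent 2 by default, configurable for
  sensitivity checks.  With a structural modulus of 500 MPa and BV/TV
  0.632 the inversion gives a 1.25 GPa material modulus.

Parameter recovery under the synthetic-record conditions (50 records,
E_eff ∈ [200, 800] MPa, yield ∈ [20, 40] MPa, 1% load noise): median
relative error ≈0.3% (modulus) and ≈1.3% (yield).

## Problem sizes and numerical choices

The test suite and the acceptance script run the simulations at ~100
voxels along the fang centreline (≈8–30k elements, 35–120k DOFs per fang),
where CG converges within the 2000-iteration budget at 1e-8; the
mesh-convergence checks compare 64 vs 128 (open-groove, closed-nonfused)
and 80 vs 160 (closed-fused — its thinner walls need ≥2 voxels) at 1e-6
with a larger iteration cap.  Morphometric recovery at the same resolution
yields: segment angle and fang length essentially exact (the landmark
polyline is exact), BV/TV within 0.04, mean wall thickness within 0.5
voxel.  These sizes were chosen so a full run completes in minutes on one
CPU; all tolerances hold with margin at finer resolution.

## What the synthetic data do and do not show

The generator reproduces the *geometric* features the measurements and
simulations respond to — curvature, taper, wall thickness, internal
cavities, phenotype-specific canal roofs — with exact ground truth.  It
does not reproduce: surface ornament (the sharp cutting edges of real
fangs), the suture's internal interface (modelled as a surface notch only),
material heterogeneity (real fang material is stiffer at the surface than
in the bulk, which is precisely why structure-level and indentation moduli
disagree), scan noise and segmentation artefacts, or replacement-fang
series.  Passing recovery tests therefore demonstrates correctness of the
measurement and simulation pipeline, not biological realism of any
individual number.  The mean lateral/parallel stress ratio measured on the
presets (~2.4–2.5) sits below the ~3 reported for real fangs, consistent
with stand-in geometry rather than scanned shapes.

## Known limitations

* The segmentation default (global Otsu) is a declared stand-in for the
  proprietary adaptive surface determination of commercial microCT
  software; an explicit threshold override is provided.
* The TV envelope (ball closing + fill) is a declared, deterministic
  definition, not a reverse-engineered reproduction of any commercial
  "advanced segmentation".
* Fully integrated trilinear hexahedra are mildly stiff in bending
  (cantilever deflection ~7% below beam theory at 4 elements through the
  thickness); the decile stress statistic is insensitive to this at the
  tested resolutions.
* The effective-modulus check against the deposited cobra-fang scan needs
  that external dataset; the pipeline path is implemented and tested on
  synthetic STL geometry.
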