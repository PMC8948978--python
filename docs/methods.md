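# Methods

This note documents the models, numerical choices, and limitations behind
`neckssm`. Units are millimetres (and mm² for variances) throughout; no
reader rescales input coordinates.

## Coordinate frame

All per-patient inputs are assumed to share one patient-space frame. The
default convention is LPS-like: +x = patient left, +y = posterior,
+z = cranial, so "anterior" is −y. The frame matters in exactly two places:
the 0° reference direction of the contour rays (patient-anterior projected
into each station's normal plane, falling back to patient-left when the
tangent is within 5° of anterior) and the left/right labelling of
deflection modes. It is configurable via `AxesConvention`.

## Tubular parametrization

* **LRA baseline.** The LRA landmark is projected onto every CLL segment
  (clamped foot points); the closest foot wins, ties resolved to the more
  proximal arc position. A landmark farther than 30 mm from the CLL aborts
  with a dedicated error — in practice that indicates a unit or frame
  mismatch, not anatomy.
* **Distal neck end.** Primary mode: the distal landmark's projection
  (necks are landmarked manually in clinical workflows). Automatic mode:
  walk distally in 1 mm steps and return the first arc position where the
  lumen diameter reaches 1.10 × the baseline diameter, refined by bisection
  to 0.1 mm. Diameter is operationalized as twice the mean of the 36 ray
  lengths: it is rotation-stable, reuses the ray machinery, and on an
  elliptical section equals twice the mean polar radius at the probe
  angles. A 1e-9 relative slack on the threshold keeps an exact
  threshold-touch at the CLL end detectable in floating point.
* **Stations.** "Ten equidistant segments" is realized as ten stations
  including both endpoints, spaced (end − baseline)/9 apart: this matches a
  picture of ten equidistantly spaced points on the CLL and gives rings at
  both anatomical boundaries. Tangents are central differences at ±0.5 mm
  of arc (equivalent to resampling at 0.5 mm), one-sided at the ends; the
  one-sided chord bias is h/2R — negligible for anatomical CLL curvature,
  ~1.4° on a deliberately sharp 10 mm-radius test arc.
* **Ray casting.** Möller–Trumbore intersection of each of the 36 in-plane
  rays against the mesh, keeping the nearest strictly positive hit (the
  station origin lies on the CLL inside the lumen, so the nearest hit is
  the local wall even in bowed necks with multiple crossings). Tolerances:
  triangles with |det| ≤ 1e-12 × |e1||e2| are treated as parallel,
  barycentric bounds are inclusive at 1e-9 (so rays through shared edges or
  vertices always register), minimum ray parameter 1e-9 mm. Because every
  hit lies in the station's normal plane, triangles not crossing that plane
  (with 1e-6 mm slack for the inclusive tolerances) are pruned before
  intersection; the pruning is exact and only a performance device. A ray
  with no hit, or a nearest hit beyond 60 mm (a mesh hole), raises an error
  naming the station and angle.

## Correspondence

Each of the 36 longitudinal columns of the grid is re-placed at equal
spacing along its own 3D polyline by linear interpolation, keeping the two
endpoint rings fixed. A single interpolation pass leaves slightly unequal
chord distances (interpolated points cut polyline corners), so the pass is
iterated to its fixed point (relative spacing spread ≤ 1e-13, ≤ 200
passes): the result has exactly equal consecutive distances — which is what
prevents adjacent rings from crossing — and makes the operation idempotent.
Smooth anatomical columns converge in a handful of passes with negligible
movement beyond the first.

Alignment is a pure translation of the grid so the CLL point at the LRA
projection sits at the origin. No rotation and no scaling: deflection modes
are only meaningful if orientation is preserved, and size is itself a
clinically relevant mode.

Shape vectors flatten the grid ring-major, then ray, then x/y/z
(10 × 36 × 3 = 1080 values).

## Shape model

PCA via economy SVD of the centered n × 1080 cohort matrix. Component
variances are squared singular values divided by n − 1 (sample-variance
convention, consistent with the n − 1 retained components of an n-shape
cohort). Components below 1e-10 × the largest variance, or below an
absolute floor of 1e-18 mm² (sub-nanometre spread is numerical noise), are
discarded. Eigenvector signs are fixed so the largest-magnitude entry of
each column is positive, making fits reproducible across linear-algebra
backends and shape orderings.

Mode meshes triangulate the unflattened grid of x̄ + s·√λ_i·φ_i as an open
tube (each inter-ring quad split along a fixed diagonal; 648 triangles for
a 10 × 36 grid). Per-mode training scores are Shapiro–Wilk tested at
α = 0.05; for non-normal modes the recommended SD range is clipped to the
empirical score range (a strongly skewed length mode may support −1 SD
rather than −3 SD on the short side). A degenerate or self-intersecting
tube at extreme s triggers a warning but the mesh is still returned.

## Evaluation

* **Compactness**: cumulative explained-variance fraction per PC count
  (empty for a zero-variance model).
* **Generalization**: leave-one-out cross-validation — refit on n − 1
  shapes, reconstruct the left-out shape by orthogonal projection onto the
  first k PCs (the minimum-RMSE linear reconstruction), score by RMSE.
* **Specificity**: sample scores b with b_i ~ N(0, λ_i) for i ≤ k
  (`numpy.random.default_rng(seed).standard_normal((n_samples, k)) ·
  √λ`, a documented stream so independent reimplementations can reproduce
  it exactly), reconstruct, and take the RMSE to the nearest training
  shape. Default 1000 samples; the seed is a required, logged parameter.
* RMSE is over the 360 corresponded 3D points (point-to-point Euclidean
  distances), not the 1080 scalar coordinates, so values read directly as
  millimetres of surface discrepancy.
* 95% confidence intervals use the normal approximation mean ± 1.96·SE.

## Synthetic cohort generator

The generator emulates the three per-patient inputs with a tube around a
smooth polynomial centerline from (0,0,0) to the distal point:

* lateral/anterior bow via the bump 4t(1−t) (offset at the apex, vanishing
  at both ends),
* distal tilt via a C¹ quadratic ramp beyond t = 0.5 whose end slope equals
  tan(tilt),
* circular cross-sections of diameter d₀(1 + taper·t) perpendicular to the
  local tangent, laid out with the same anterior-referenced frame the
  parametrization uses — so `analytic_ring` is an exact closed-form oracle
  for contour points of noise-free shapes,
* vertex-wise radial Gaussian noise (radial, so tubes stay star-shaped and
  valid),
* meshes are closed circumferentially, capped with rim fans (no extra
  vertices) and extend a 4% axial margin past both landmarks, mirroring
  real lumen segmentations that continue beyond the neck and keeping the
  wall well-defined at the boundary stations. Default resolution is 40
  axial × 72 circumferential samples (faceting error ≈ 0.011 mm at radius
  12 mm, well below typical segmentation noise).

Tubes whose centerline bends more tightly than the local tube radius
(curvature radius < 1.05 × radius, checked on 201 dense samples) are
rejected as self-intersecting; cohort draws that hit the check are redrawn,
and a spec whose rejections exceed the accepted draws aborts.

**Shape-space calibration.** Cohort mode variances are specified in shape
space — mm² per contour point of the processed (rearranged, aligned) shape
vector — because the five generator parameters live in incommensurable
units (mm of length vs degrees of tilt) with very different shape
sensitivities. For each mode the generator measures the per-point RMS
shape displacement per unit parameter by central finite differences of the
analytic shape functional at the cohort mean, and divides the requested
shape-space SD by that sensitivity to get the parameter SD. The vertex
noise SD is calibrated empirically inside the call: probe meshes with unit
noise are parametrized and the induced per-point contour variance measured,
then scaled so the noise share of total shape variance equals
`noise_variance_fraction`.

**Default cohort.** n = 97; mean neck 24 mm diameter × 30 mm length,
straight and untapered; mode variances proportional to 51:30:12:2:2
totalling 9 mm² per point (per-point SD 3 mm), noise share 5%. The
proportions make the recovered variance spectrum directly comparable to the
generative truth; the absolute scale was chosen once for anatomical
plausibility — length SD ≈ 3.7 mm, apex deflection SDs ≈ 1.7/1.1 mm,
diameter SD ≈ 0.9 mm, distal tilt SD ≈ 4.3°, giving <1% self-intersection
rejections. With n = 97 the per-seed sampling fluctuation of the first
variance fraction is ±2–3 percentage points (eigenvalue estimates fluctuate
by √(2/(n−1)) ≈ 14% relative), so spectrum-recovery checks average over
seeds.

**What the generator does not emulate:** thrombus and calcification,
branch vessels, non-circular (e.g. strongly elliptical or lobulated)
cross-sections, imaging/segmentation artefacts beyond radial Gaussian
noise, and correlated inter-parameter anatomy (modes are drawn
independently). Passing tests therefore demonstrate the correctness of the
pipeline's geometry, correspondence, decomposition, and evaluation
machinery — not clinical validity of any particular fitted model.

## Degenerate inputs and tie-breaks

* Quads in OBJ files are split along their first diagonal; zero-area
  triangles are dropped on load with a warning.
* Duplicate consecutive CLL points are collapsed with a warning; fewer than
  two surviving points is an error.
* Equidistant projection feet tie-break to the smaller arc position.
* An identical-shape cohort fits to zero components; evaluation then
  reports reconstruction errors relative to the mean shape (≈ 0) and an
  empty compactness curve.
* Leave-one-out folds that retain fewer components than requested project
  onto what the fold provides.

## Problem sizes

Default test and acceptance runs use 97-shape cohorts at 12 × 36 mesh
resolution in the test suite (where only structure matters) and the full
40 × 72 default in the acceptance script, with five seeds averaged for
spectrum recovery; a full cohort generates, parametrizes and fits in a few
seconds on one CPU.
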