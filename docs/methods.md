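# Methods

`fluororeg` implements an intra-operative 2D/3D registration framework for
robot-assisted fracture surgery: given a CT-derived triangle mesh of a bone
fragment and two calibrated fluoroscopic views of the fragment with an
orthopaedic pin and a bead fiducial (the *registration tool*, RT) attached,
it estimates the rigid pose of the fragment relative to the pin. That
pin-to-fragment transform is what a navigation system needs, because the
pin is the only part of the construct that remains trackable once the
fluoroscope is taken away.

This note records the models, the numerical choices, and what the
synthetic validation does and does not demonstrate.

## Imaging model

The C-arm is a pinhole camera: X-ray source at the camera origin, optical
axis +z, detector plane at `z = SID` (source-to-image distance, the focal
length of the model). Image coordinates are `(u, v)` px, origin top-left,
principal point at the detector centre. The default model is a mobile
image-intensifier C-arm: SID 980 mm, detector 230 mm, pixel pitch
0.224 mm/px, image 1030×1030 px. All lengths are mm, image coordinates px,
angles degrees at the API surface; rotations are stored as matrices and
poses as 4×4 row-major homogeneous transforms in JSON.

Image-intensifier pincushion distortion is modelled (synthesis side only)
as an even-power radial polynomial in pixel coordinates,
`r' = r (1 + k1 r² + k2 r⁴)` about a centre. The *correction* recovered by
calibration is deliberately independent of this parametric form.

## Grid calibration

A plate of 10-mm ball bearings on a 22-mm square lattice is laid directly
on the detector (unit magnification) and imaged once. The pipeline:

1. **Bead segmentation** — Otsu threshold (polarity auto-detected),
   connected components, intensity-weighted centroids. The bead count must
   match the grid, otherwise a coverage error is raised.
2. **Lattice matching** — the detected lattice's rotation is estimated
   from folded nearest-neighbour direction statistics, its pitch from
   nearest-neighbour distances; each centroid is rounded to an integer
   lattice node (bijectively, or a matching error is raised) and paired
   with the ideal axis-aligned lattice centred at the principal point.
3. **Pixel size** — the lattice is fitted with a similarity + single-
   coefficient radial model, `detected ≈ c + R·(pitch·g)(1 + a·|pitch·g|²)`
   over all beads. The pitch of this model is the scale *at the lattice
   centre*, so pincushion distortion does not bias it; pixel size =
   spacing / pitch. A simpler plain-pitch estimator (optionally restricted
   to the central sub-lattice) is kept as `estimate_pixel_size` for
   transparency; the model-based estimator is what `GridCalibration.fit`
   uses because a relative scale error ε in the pixel size becomes a depth
   error ≈ ε × standoff (~0.7 mm per 0.1 %) downstream.
4. **Distortion correction** — a global bivariate polynomial (total degree
   3 by default, configurable 2–5) per output coordinate, mapping distorted
   px to ideal px, least-squares fitted on the bead correspondences with
   normalised coordinates. Degree 3 resolves an intensifier-scale
   pincushion (a few px at the periphery) to < 0.1 px; the quality metric
   we ship is the held-out border-ring residual.

Calibration is assumed orientation-independent (one calibration reused for
all C-arm angulations); gravity-dependent distortion drift is out of scope.

## Fiducial view-pose estimation

The RT carries three radiopaque beads at (0,0,25), (25,0,40), (0,24,60) mm
and mounts uniquely on the pin (tip at (0,0,−60) mm, so pin frame ≡ RT
frame). The four points are non-coplanar (tetrahedron volume ≫ 50 mm³) and
their six pairwise distances are pairwise distinct by > 2 mm, which makes
single-view labelling well-posed.

Detection: metal is thresholded at 0.55 of the image maximum; the most
elongated component is the pin, compact components are beads. Bead centres
are refined from a core-weighted centroid by per-ray mid-level edge
crossings with a circle fit — each ray uses its *own* inside/outside
levels and rays without a flat outside plateau are discarded, so a bone
silhouette edge passing under a bead does not bias the centre (≤ 0.05 px
on clean renders). The pin tip (the flat bottom end, identified as the end
farther from the bead centroid) is localised by the intensity-gradient
peak along the pin axis with alternating perpendicular re-centring
(~0.1–0.3 px). Labelling matches the six observed/model distance ratios
over the six bead permutations, with a trial-pose tie-break when ratios
are close. A manual pathway (clicked coordinates in a detections JSON)
bypasses all of this.

Pose: Grunert's perspective-3-point on the beads (the elimination quartic
is assembled numerically by evaluating the resultant at five nodes —
exactly determining a degree-4 polynomial — rather than transcribing
closed-form coefficients), candidate disambiguation by pin-tip
reprojection inside a 20 px gate, then joint Levenberg–Marquardt
refinement on all four points. The tip enters with a weight equal to the
variance ratio `(cov + 0.1²)/(cov + 0.35²)` where `cov` is the detections'
localisation covariance: with precise detections the beads dominate (the
tip's flat-end localisation is ~3× noisier), under heavy jitter all four
features become comparably informative and the tip's long lever arm is
kept for depth. Reported reprojection RMS is always the unweighted RMS
over the four features.

## Contour registration

Both views are posed in the RT frame, so registering the fragment mesh to
the two segmented contours directly yields the pin-to-fragment transform.

* **Model silhouette.** The outline of the projected mesh is the boundary
  of the union of its projected triangles. `extract_silhouette` computes
  that union exactly in vector geometry (shapely) and returns an ordered
  contour. Inside the optimisation loop a faster exact sampler is used:
  occluding edges (facet front/back flips w.r.t. the source) are sampled
  in projection and samples covered by any other facet's projection are
  discarded — for a closed surface every interior fold point is covered by
  the far side of the solid, so the survivors lie exactly on the outer
  outline. Each sample carries its generating 3D surface point.
* **Segmentation.** The initial contour (the thresholded fragment blob
  boundary, standing in for the projection of the coarsely placed model)
  is refined by moving each sample along its normal to the strongest
  intensity-gradient peak within ±15 px (0.5 px steps, cubic image
  interpolation, quadratic sub-pixel peak). Samples without a gradient
  above 5 % of the dynamic range per px — occluded or washed out — are
  dropped; more than 60 % dropped fails the view (the overlapping-fragment
  situation). Known metal regions (pin corridor, bead disks, predicted
  from the estimated view pose) are excluded. The result is a periodic
  cubic smoothing spline parameterised by normalised arc length; the
  smoothing allowance tracks the expected contour noise
  (`max(0.15, 0.4 σ)` px). Spline spans that merely bridge dropped samples
  are flagged unsupported and are not matched against.
* **Cost.** `C(θ) = Σ_views mean_i d_i²` where `d_i` is the signed
  distance from silhouette sample i to the segmented spline along the
  contour normal at the closest point (dense-polyline + KD-tree query),
  200 samples per view per iteration, Huber weight at 3 px against
  outliers, samples near the image border or matched to unsupported spline
  spans excluded.
* **Optimisation.** Damped Gauss–Newton over 6 DOF (rotation about the
  fragment centroid + translation), correspondences re-established every
  iteration, with the standard fixed-contour-generator first-order
  Jacobian (silhouette points treated as material surface points for the
  derivative; the sliding of the generator itself is second order).
  Accepted steps never increase the cost; convergence at relative cost
  change < 1e-8 or when no damped step improves; 200-iteration budget.
* **Coarse alignment.** The surgeon's manual placement is replaced by a
  seeded randomised search: 200 pose samples around an initial guess
  (translation from triangulating the two contour centroids; rotation from
  the nominal pin-attachment prior), ±15 mm/±15° per axis, a wide stage
  then a 1/3-range refinement stage, scored by the registration cost on a
  sparser outline sampling, followed by a few damped Gauss–Newton polish
  steps. Deterministic per seed. A user-supplied initial pose bypasses the
  search.

The end-to-end pipeline retries the coarse search (up to 3 deterministic
restarts) when the achieved contour RMS exceeds a plausibility gate of
2.2 × (σ_contour + 0.6) px, and keeps the lowest-cost result; a view whose
fiducial features cannot be recovered is re-acquired (re-rendered with a
shifted noise stream), mirroring what an operator would do with an
unusable exposure.

## Evaluation

Accuracy is the **surface target registration error**: n points (default
100) drawn area-uniformly from the faces labelled as fracture surface,
mapped through the ground-truth and the estimated fragment pose; the
per-point distances are reported as mean ± sd. The sd is across points
within a run; across-run aggregation reports the mean of run means (both
are emitted). Fracture surfaces are the clinically relevant target: they
are what must be matched when the fragments are reduced.

The intra-operative chain `RFM target = (RFM→pin) × (image→fragment) ×
planned pose` is provided (`rfm_target_pose`), plus translational RMSE
over probe points and geodesic-angle rotational RMSE for achieved-vs-
desired pose sets. The surgeon-read angulation measurements of the
physical study are not reproducible from text and are replaced by the
standard geodesic metric.

## Synthetic phantom

The generator emulates the physical study's inputs at desk scale:

* **Bone.** A generalised cylinder along y: circular shaft (radius 14 mm)
  with 12 % antero-posterior flattening and a 6-mm anterior bow, flaring
  into a two-lobed condylar mass (`r(θ) = R(y)(1 + A(y) cos²θ)`), 130 mm
  long. A straight circular shaft would leave axial spin nearly
  silhouette-invariant; the bow, the flattening and the fracture geometry
  below restore the observability a real bone has.
* **Fracture.** One "transverse" supracondylar cut — deliberately oblique
  (slopes 0.07/0.14) and jagged (two-harmonic undulation, 2.5 mm base
  amplitude, 3+5 lobes, like a real fracture line) — separates the shaft
  fragment FEM; a sagittal (T) or helicoidally twisted (Y analogue) axial
  cut splits the condylar block into F1 and F2. All cut faces are labelled
  fracture surface. Meshes are watertight by construction and vertices are
  quantised to the CT voxel (0.58 × 0.58 × 0.75 mm) by default.
* **Fiducials.** Each fragment gets a pin + RT at a nominal anatomical
  attachment with per-seed randomisation (±10° cone tilt, ±10° clocking,
  ±4 mm entry jitter, 10 mm insertion depth). The ground-truth fragment
  pose in its RT frame is the inverse of this attachment. The pipeline's
  orientation prior is the *nominal* attachment only.
* **Views.** The C-arm orbits the world y axis at a 700-mm source-to-
  isocentre distance; AP = 90°, LAT = 60°, per-fragment isocentre between
  the fragment and its fiducial. Rendering is silhouette shading, not
  X-ray transport: fragment shadow 0.45, pin 0.92, beads 1.0, "over"-
  composited (so anti-aliased edge ramps stay symmetric over any
  background — max-compositing was measured to bias edge localisation by
  ~0.25 px), supersampled polygon rasterisation with a measured
  0.3-subpixel erosion compensating PIL's outline stroke, 1-px Gaussian
  optics blur. This suffices because every downstream operator consumes
  edges and blobs. Ground truth (camera poses, feature positions,
  silhouettes) is recorded pre-noise.
* **Noise profiles.** `clean` (nothing), `phantom-like` (pixel noise 1 %
  full scale, feature jitter σ 0.25 px, smooth correlated contour
  perturbation σ 0.5 px, no occlusion) and `cadaver-like` (2 %, 0.5 px,
  1.5 px, plus an overlapping-structure band hiding 25 % of the LAT
  contour). The profile parameters are calibration knobs chosen to emulate
  the clean→degraded pattern between bench and cadaveric imaging; they are
  not measurements of any particular device. Synthesis distortion is off
  in the shipped profiles (the correction path still runs and is exercised
  by dedicated round-trip tests with distortion enabled).

What passing these simulations shows: the geometry/optimisation chain is
correct and unbiased at the sub-0.1-mm level, and its degradation under
plausible localisation/contour noise stays inside the accuracy envelope a
physical system of this design achieved. What it does not show: robustness
to real soft-tissue clutter, scatter, automatic-exposure variation,
anatomical shape variation, or segmentation of real CT — the renders are
deliberately schematic and the bone is procedural, not an atlas.

## Problem sizes and determinism

The shipped study sizes are 20 seeds × 3 fragments × 2 views per noise
profile, 5 seeds for the clean fixed-point check, 100 sTRE points, 200
contour samples per view. One fragment registers in a few seconds on one
core. Every stage draws from `numpy` generators seeded via
`SeedSequence` from the experiment seed; repeated runs are bit-identical,
including rendered images and CSV outputs.

## Known limitations

* The pin-tip localisation (~0.3 px) is the weakest feature; the P4P
  refinement down-weights it accordingly, and view-pose depth is the
  dominant clean-data error term.
* Single-view registration is supported but depth-degenerate (this is a
  feature of the physics, demonstrated in the test suite, not a bug).
* The coarse search assumes the true pose within ±15 mm/±15° of the
  prior; a grossly wrong prior requires the manual initial-pose pathway.
* T/Y fracture patterns only; comminution (more than three fragments) is
  out of scope.
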