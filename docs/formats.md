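# File formats

All artefacts are plain text or standard binary imaging/mesh formats so
runs can be archived and diffed.

## Meshes — STL (+ label sidecar)

Fragment surfaces are STL (binary or ASCII), units mm, as produced by CT
segmentation pipelines. STL has no face attributes, so fracture-surface
labels live in a sidecar `<name>.stl.labels.json`:

```json
{"fracture_faces": [12, 13, 14, ...]}
```

`fracture_faces` are 0-based face indices into the STL triangle order.
`fluororeg.io.read_mesh` returns `(trimesh.Trimesh, labels-or-None)` and
validates the index range.

## Transforms — JSON

Rigid transforms are row-major 4×4 homogeneous matrices at full double
precision:

```json
{"matrix": [[r, r, r, t], [r, r, r, t], [r, r, r, t], [0, 0, 0, 1]]}
```

`read_transform` rejects matrices whose rotation block is not orthonormal
within 1e-6 (or whose bottom row is not `0 0 0 1`).

## Images — 16-bit TIFF/PNG

Fluoroscopic renders and calibration images are written as 16-bit
grayscale, full scale = 1.0 in the internal attenuation convention (metal
bright on dark background). `read_image` rescales 8/16-bit input to
float [0, 1].

## C-arm model — JSON

```json
{
  "sid": 980.0,
  "pixel_size": 0.224,
  "detector_diameter": 230.0,
  "principal_point": [515.0, 515.0],
  "image_shape": [1030, 1030],
  "distortion": {"coefficients": [6e-08], "center": [515.0, 515.0]}
}
```

`distortion` (optional, synthesis only): radial polynomial coefficients
k1, k2, ... in px^-2, px^-4, ... about `center`.

## Fiducial geometry — JSON

```json
{
  "bead_centers": [[0,0,25], [25,0,40], [0,24,60]],
  "pin_tip": [0,0,-60],
  "labels": ["bead1","bead2","bead3"],
  "pin_radius": 2.0,
  "pin_top": [0,0,5]
}
```

Coordinates in mm in the registration-tool frame (≡ pin frame).

## Detections / image pose / calibration / registration results — JSON

* `FeatureDetections`: `{"points": [[u,v]×4], "covariance_px2": s}` —
  ordered bead1..3, pin tip; this is also the manual-input bypass format.
* `ImagePose`: pose (4×4) + `rms_reprojection` + `per_point_residuals`.
* `CalibrationResult`: polynomial correction (degree, coefficients,
  normalisation, fit RMS), pixel-size estimate, per-bead residuals, grid.
* `RegistrationResult`: fragment pose, pin-to-fragment pose (both 4×4),
  initial/final cost (px²), iterations, convergence flag, per-view
  contour RMS.

## Experiment tables — CSV

`run-experiment` writes one row per (seed, fragment):
`seed, fragment, stre_mean_mm, stre_sd_mm, n_points, final_cost_px2,
iterations, converged, attempts, pixel_size_mm, elapsed_s, error`.
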