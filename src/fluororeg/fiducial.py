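"""Fluoroscopic-view pose estimation from the registration-tool fiducial.

The registration tool (RT) is a radiolucent body holding three radiopaque
beads; it mounts on an orthopaedic pin in a unique way so the pin and RT
frames coincide.  Each fluoroscopic view images the three beads and the
pin's flat bottom end ("tip"), giving four labelled 2D-3D correspondences
from which the 6-DOF pose of the view relative to the RT/pin frame is
estimated:

1. perspective-3-point (Grunert) on the beads, yielding up to four
   candidate poses;
2. disambiguation by reprojecting the pin tip (gate, default 20 px);
3. joint nonlinear least-squares refinement on all four points.

Feature detection is automated (threshold + component analysis +
geometric labelling); a manual pathway exists by constructing
:class:`FeatureDetections` directly (e.g. from clicked coordinates in a
JSON file).
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.optimize import least_squares
from scipy.spatial.transform import Rotation
from skimage.measure import label as sk_label
from skimage.measure import regionprops

from .errors import (
    DegenerateConfigurationError,
    DetectionError,
    LabelingError,
    ConvergenceError,
)
from .geometry import CArmModel, RigidTransform, project_points

__all__ = [
    "FiducialGeometry",
    "FeatureDetections",
    "ImagePose",
    "detect_features",
    "estimate_image_pose",
]


@dataclass(frozen=True)
class FiducialGeometry:
    """Bead centres and pin tip in the registration-tool frame (mm).

    The four points must be non-coplanar (tetrahedron volume > 50 mm^3) and
    have pairwise distances all distinct by more than 2 mm so the beads can
    be labelled unambiguously from a single projection.
    """

    bead_centers: np.ndarray  # (3, 3) mm
    pin_tip: np.ndarray  # (3,) mm
    labels: tuple = ("bead1", "bead2", "bead3")
    pin_radius: float = 2.0  # mm, for synthesis/rendering
    pin_top: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 10.0]))

    def __post_init__(self):
        object.__setattr__(self, "bead_centers", np.asarray(self.bead_centers, float))
        object.__setattr__(self, "pin_tip", np.asarray(self.pin_tip, float))
        object.__setattr__(self, "pin_top", np.asarray(self.pin_top, float))
        b, tip = self.bead_centers, self.pin_tip
        vol = abs(np.linalg.det(np.stack([b[1] - b[0], b[2] - b[0], tip - b[0]]))) / 6.0
        if vol <= 50.0:
            raise LabelingError(f"fiducial points nearly coplanar (volume {vol:.1f} mm^3)")
        pts = np.vstack([b, tip])
        d = [
            np.linalg.norm(pts[i] - pts[j])
            for i in range(4)
            for j in range(i + 1, 4)
        ]
        d = np.sort(d)
        if np.diff(d).min() <= 2.0:
            raise LabelingError("pairwise fiducial distances not distinct by > 2 mm")

    @property
    def points(self) -> np.ndarray:
        """All four model points, ordered bead1..3, pin tip: (4, 3) mm."""
        return np.vstack([self.bead_centers, self.pin_tip])

    @classmethod
    def from_dict(cls, d: dict) -> "FiducialGeometry":
        return cls(
            bead_centers=np.asarray(d["bead_centers"], float),
            pin_tip=np.asarray(d["pin_tip"], float),
            labels=tuple(d.get("labels", ("bead1", "bead2", "bead3"))),
            pin_radius=float(d.get("pin_radius", 2.0)),
            pin_top=np.asarray(d.get("pin_top", [0.0, 0.0, 10.0]), float),
        )

    def to_dict(self) -> dict:
        return {
            "bead_centers": self.bead_centers.tolist(),
            "pin_tip": self.pin_tip.tolist(),
            "labels": list(self.labels),
            "pin_radius": self.pin_radius,
            "pin_top": self.pin_top.tolist(),
        }

    @classmethod
    def load(cls, path) -> "FiducialGeometry":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass
class FeatureDetections:
    """Labelled 2D feature locations in one view, ordered bead1..3, pin_tip."""

    points: np.ndarray  # (4, 2) px
    covariance_px2: float = 0.0  # isotropic localisation variance, informational

    def __post_init__(self):
        self.points = np.asarray(self.points, float).reshape(4, 2)

    @property
    def beads(self) -> np.ndarray:
        return self.points[:3]

    @property
    def pin_tip(self) -> np.ndarray:
        return self.points[3]

    def to_dict(self) -> dict:
        return {"points": self.points.tolist(), "covariance_px2": self.covariance_px2}

    @classmethod
    def from_dict(cls, d: dict) -> "FeatureDetections":
        return cls(np.asarray(d["points"], float), float(d.get("covariance_px2", 0.0)))

    @classmethod
    def load(cls, path) -> "FeatureDetections":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def save(self, path):
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


@dataclass
class ImagePose:
    """Estimated view pose (RT frame -> camera frame) with reprojection stats."""

    pose: RigidTransform
    rms_reprojection: float  # px over the 4 features
    per_point_residuals: np.ndarray  # (4,) px

    def to_dict(self) -> dict:
        return {
            "pose": self.pose.to_dict(),
            "rms_reprojection": self.rms_reprojection,
            "per_point_residuals": self.per_point_residuals.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ImagePose":
        return cls(
            pose=RigidTransform.from_dict(d["pose"]),
            rms_reprojection=float(d["rms_reprojection"]),
            per_point_residuals=np.asarray(d["per_point_residuals"], float),
        )

    @classmethod
    def load(cls, path) -> "ImagePose":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def save(self, path):
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


# ---------------------------------------------------------------------------
# feature detection
# ---------------------------------------------------------------------------

def _axis_profile(img, origin, direction, ts, step_normal=0.0):
    """Sample the image along origin + t*direction with cubic interpolation."""
    pts = origin[None, :] + ts[:, None] * direction[None, :]
    # map_coordinates wants (row, col) = (v, u)
    return ndimage.map_coordinates(
        img, [pts[:, 1], pts[:, 0]], order=3, mode="nearest"
    )


def _refine_disk_center(img, c0: np.ndarray, r_est: float, n_rays: int = 24) -> np.ndarray:
    """Sub-pixel disk centre from per-ray mid-level edge crossings.

    Each ray's edge position is the crossing of the midpoint between that
    ray's own inside and outside intensity levels, so a background step
    under the disk (e.g. the bone silhouette) does not bias the centre.
    """
    c = np.asarray(c0, float).copy()
    ang = np.linspace(0.0, 2 * np.pi, n_rays, endpoint=False)
    dirs = np.stack([np.cos(ang), np.sin(ang)], axis=1)
    ts = np.arange(r_est - 4.0, r_est + 4.01, 0.25)
    for _ in range(3):
        pts = c[None, None, :] + ts[None, :, None] * dirs[:, None, :]
        prof = ndimage.map_coordinates(
            img, [pts[..., 1].ravel(), pts[..., 0].ravel()], order=1, mode="nearest"
        ).reshape(n_rays, len(ts))
        inside = prof[:, 0]
        outside = prof[:, -1]
        level = 0.5 * (inside + outside)
        # first crossing below the mid level, linearly interpolated
        below = prof <= level[:, None]
        edge = np.full(n_rays, np.nan)
        for i in range(n_rays):
            k = np.argmax(below[i])
            if k == 0 or not below[i].any():
                continue
            p0, p1 = prof[i, k - 1], prof[i, k]
            frac = (level[i] - p0) / (p1 - p0) if p1 != p0 else 0.5
            edge[i] = ts[k - 1] + frac * 0.25
        # a ray is usable only with clear contrast and a flat outside
        # plateau (otherwise it also crosses the bone-silhouette step and
        # its mid-level is meaningless)
        flat = np.abs(prof[:, -1] - prof[:, -7]) < 0.02
        ok = np.isfinite(edge) & (np.abs(inside - outside) > 0.1) & flat
        if ok.sum() < 6:
            return c
        # algebraic circle fit to the edge points
        P = c + edge[ok, None] * dirs[ok]
        A = np.column_stack([2 * P, np.ones(ok.sum())])
        b = (P**2).sum(axis=1)
        sol, *_ = np.linalg.lstsq(A, b, rcond=None)
        c = sol[:2]
    return c


def _label_beads(
    bead_px: np.ndarray, tip_px: np.ndarray, fid: FiducialGeometry, carm: CArmModel
) -> np.ndarray:
    """Order 3 detected bead centroids as bead1..3.

    Primary criterion: consistency of the six observed/model pairwise
    distance ratios (beads + pin tip).  If two permutations score within
    20% of each other — projective foreshortening can make ratios
    deceptive — the tie is broken by running the full pose estimation for
    the contenders and keeping the lower reprojection RMS.
    """
    pairs = ((0, 1), (0, 2), (1, 2), (0, 3), (1, 3), (2, 3))
    model = np.vstack([fid.bead_centers, fid.pin_tip])
    dm = np.array([np.linalg.norm(model[i] - model[j]) for i, j in pairs])
    perms = list(itertools.permutations(range(3)))
    scores = []
    for perm in perms:
        p = np.vstack([bead_px[list(perm)], tip_px])
        do = np.array([np.linalg.norm(p[i] - p[j]) for i, j in pairs])
        ratio = do / dm
        scores.append(float(np.std(ratio) / np.mean(ratio)))
    order = np.argsort(scores)
    if scores[order[1]] > 1.2 * scores[order[0]] + 1e-9:
        return bead_px[list(perms[order[0]])]
    # tie-break by trial pose estimation
    best, best_rms = None, np.inf
    for k in order[:3]:
        cand = FeatureDetections(np.vstack([bead_px[list(perms[k])], tip_px]))
        try:
            pose = estimate_image_pose(cand, fid, carm)
        except (DegenerateConfigurationError, ConvergenceError):
            continue
        if pose.rms_reprojection < best_rms:
            best_rms, best = perms[k], pose.rms_reprojection
            best, best_rms = perms[k], pose.rms_reprojection
    if best is None:
        raise LabelingError("ambiguous bead labelling (no permutation yields a pose)")
    return bead_px[list(best)]


def detect_features(
    image, carm: CArmModel, fid: FiducialGeometry, params: dict | None = None
) -> FeatureDetections:
    """Locate the three beads and the pin tip in a (calibrated) view.

    The metal features are segmented by thresholding; components are
    classified by shape (beads: compact, pin: elongated).  Bead centroids
    are intensity weighted; the pin tip is the end of the pin segment that
    terminates *inside* the bone shadow, localised to sub-pixel accuracy by
    the intensity-gradient peak along the pin axis.

    Raises
    ------
    DetectionError
        If fewer than 3 beads plus a pin are found.
    LabelingError
        If the beads cannot be labelled unambiguously.
    """
    p = {"metal_threshold_frac": 0.55, "min_bead_area_px": 30.0}
    if params:
        p.update(params)
    img = np.asarray(image, float)
    thr = p["metal_threshold_frac"] * img.max()
    mask = img > thr
    labels = sk_label(mask)
    props = regionprops(labels, intensity_image=img)
    props = [r for r in props if r.area >= p["min_bead_area_px"]]
    if not props:
        raise DetectionError("no metal features found (fiducial outside field of view?)")
    # pin: the most elongated sufficiently-large component
    elong = [r.axis_major_length / max(r.axis_minor_length, 1.0) for r in props]
    pin_i = int(np.argmax(elong))
    if elong[pin_i] < 3.0:
        raise DetectionError("no elongated pin component found")
    pin = props[pin_i]
    beads = [r for i, r in enumerate(props) if i != pin_i]
    beads = [r for r in beads if r.axis_major_length / max(r.axis_minor_length, 1.0) < 2.0]
    if len(beads) != 3:
        raise DetectionError(f"expected 3 bead components, found {len(beads)}")

    # centroid over the bright bead core, then ray-based edge refinement:
    # the core centroid is robust but pulled ~0.2 px when the bone edge
    # passes under the disk (blur mixes a stepped background into the
    # outer ring); per-ray mid-level crossings use local inside/outside
    # levels and cancel that
    bead_px = []
    for r in beads:
        vv, uu = r.coords[:, 0], r.coords[:, 1]
        vals = img[vv, uu]
        w = np.clip(vals - 0.7 * vals.max(), 0.0, None)
        c0 = np.array([(uu * w).sum() / w.sum(), (vv * w).sum() / w.sum()])
        r_est = np.sqrt(r.area / np.pi)
        bead_px.append(_refine_disk_center(img, c0, r_est))
    bead_px = np.asarray(bead_px)

    # pin axis from second moments of the component
    vv, uu = pin.coords[:, 0], pin.coords[:, 1]
    pts = np.stack([uu, vv], axis=1).astype(float)
    c = pts.mean(axis=0)
    cov = np.cov((pts - c).T)
    evals, evecs = np.linalg.eigh(cov)
    axis = evecs[:, np.argmax(evals)]
    t = (pts - c) @ axis
    t_lo, t_hi = t.min(), t.max()

    # the tip is the pin end farthest from the beads (the other end carries
    # the registration-tool body holding the beads)
    bead_c = bead_px.mean(axis=0)
    ends = [c + t_lo * axis, c + t_hi * axis]
    which = int(np.argmax([np.linalg.norm(e - bead_c) for e in ends]))
    tend, sgn = ((t_lo, -1.0), (t_hi, +1.0))[which]

    # sub-pixel tip: alternate axial gradient-peak localisation along a line
    # through the current lateral centre with perpendicular re-centring, so
    # the axial profile runs through the middle of the flat pin end
    perp = np.array([-axis[1], axis[0]])
    t_tip, lateral = tend, 0.0
    ss = np.arange(-8.0, 8.01, 0.25)
    for _ in range(3):
        base = c + lateral * perp
        ts = t_tip + np.arange(-8.0, 8.01, 0.25) * sgn
        prof = _axis_profile(img, base, axis, ts)
        grad = np.abs(np.gradient(prof))
        k = int(np.argmax(grad))
        if 0 < k < len(grad) - 1:
            denom = grad[k - 1] - 2 * grad[k] + grad[k + 1]
            delta = 0.5 * (grad[k - 1] - grad[k + 1]) / denom if denom != 0 else 0.0
        else:
            delta = 0.0
        t_tip = ts[k] + np.clip(delta, -1, 1) * 0.25 * sgn
        inner = c + (t_tip - sgn * 5.0) * axis + lateral * perp
        prof_perp = _axis_profile(img, inner, perp, ss)
        w = np.clip(prof_perp - thr, 0.0, None)
        if w.sum() > 0:
            lateral += float((ss * w).sum() / w.sum())
    tip = c + t_tip * axis + lateral * perp

    bead_px = _label_beads(bead_px, tip, fid, carm)
    return FeatureDetections(points=np.vstack([bead_px, tip]))


# ---------------------------------------------------------------------------
# perspective-n-point
# ---------------------------------------------------------------------------

def _bearings(carm: CArmModel, uv: np.ndarray) -> np.ndarray:
    """Unit rays through the source for pixel coordinates (no distortion)."""
    xy = (uv - np.asarray(carm.principal_point)) * carm.pixel_size
    d = np.column_stack([xy, np.full(len(xy), carm.sid)])
    return d / np.linalg.norm(d, axis=1)[:, None]


def _p3p_grunert(f: np.ndarray, P: np.ndarray) -> list[np.ndarray]:
    """All P3P solutions (camera-frame point triples) for rays f and points P.

    Grunert's formulation: with u = s2/s1, v = s3/s1, eliminating u gives a
    quartic in v.  The quartic's coefficients are obtained by evaluating the
    (exactly degree-4) resultant polynomial at five nodes and solving the
    Vandermonde system, avoiding hand-transcribed coefficient formulas.
    """
    a = np.linalg.norm(P[1] - P[2])
    b = np.linalg.norm(P[0] - P[2])
    c = np.linalg.norm(P[0] - P[1])
    ca = float(f[1] @ f[2])  # opposite a
    cb = float(f[0] @ f[2])  # opposite b
    cg = float(f[0] @ f[1])  # opposite c
    A = (a * a - c * c) / (b * b)
    B = c * c / (b * b)

    def u_num(v):
        return A * (1 + v * v - 2 * v * cb) - v * v + 1

    def u_den(v):
        return 2 * (cg - v * ca)

    def resultant(v):
        # G(v) * u_den(v)^2, a quartic in v
        un, ud = u_num(v), u_den(v)
        return ud * ud + un * un - 2 * un * ud * cg - B * (1 + v * v - 2 * v * cb) * ud * ud

    nodes = np.array([-2.0, -1.0, 0.0, 1.0, 2.0])
    vals = np.array([resultant(v) for v in nodes])
    V = np.vander(nodes, 5)  # columns v^4 .. v^0
    coeffs = np.linalg.solve(V, vals)
    roots = np.roots(coeffs)
    sols = []
    for v in roots:
        if abs(v.imag) > 1e-8 * max(1.0, abs(v.real)):
            continue
        v = float(v.real)
        den = u_den(v)
        if abs(den) < 1e-12:
            continue
        u = u_num(v) / den
        s1_sq = b * b / (1 + v * v - 2 * v * cb)
        if s1_sq <= 0:
            continue
        s1 = np.sqrt(s1_sq)
        s2, s3 = u * s1, v * s1
        if s1 <= 0 or s2 <= 0 or s3 <= 0:
            continue
        sols.append(np.stack([s1 * f[0], s2 * f[1], s3 * f[2]]))
    return sols


def _absolute_orientation(P: np.ndarray, Q: np.ndarray) -> RigidTransform:
    """Rigid transform mapping points P onto Q (Kabsch/Procrustes)."""
    cp, cq = P.mean(axis=0), Q.mean(axis=0)
    H = (P - cp).T @ (Q - cq)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    return RigidTransform(R, cq - R @ cp, validate=False)


def _refine_pose(
    pose0: RigidTransform,
    fid: FiducialGeometry,
    det: FeatureDetections,
    carm: CArmModel,
    tip_weight: float,
) -> RigidTransform:
    X = fid.points
    w = np.array([1.0, 1.0, 1.0, tip_weight])[:, None]

    def residuals(x):
        R = Rotation.from_rotvec(x[:3]).as_matrix()
        pose = RigidTransform(R, x[3:], validate=False)
        uv = project_points(carm, pose, X, apply_dist=False)
        return ((uv - det.points) * w).ravel()

    x0 = np.concatenate(
        [Rotation.from_matrix(pose0.rotation).as_rotvec(), pose0.translation]
    )
    sol = least_squares(residuals, x0, method="lm", xtol=1e-14, ftol=1e-14)
    if not sol.success:
        raise ConvergenceError(f"pose refinement did not converge: {sol.message}")
    return RigidTransform(
        Rotation.from_rotvec(sol.x[:3]).as_matrix(), sol.x[3:], validate=False
    )


def estimate_image_pose(
    det: FeatureDetections,
    fid: FiducialGeometry,
    carm: CArmModel,
    gate_px: float = 20.0,
    tip_weight: float | None = None,
) -> ImagePose:
    """Perspective-4-point pose of a view relative to the RT/pin frame.

    P3P candidates from the three beads are gated by pin-tip reprojection
    (``gate_px``), each survivor is refined by joint least squares on all
    four correspondences, and the solution with the lowest reprojection RMS
    is returned.

    The pin tip enters the refinement with ``tip_weight`` < 1: its
    flat-end localisation noise (~0.35 px) is several times a bead
    centroid's (~0.1 px).  By default the weight is derived from the
    detections' localisation covariance as the variance ratio
    ``(cov + 0.1^2) / (cov + 0.35^2)``: with little external jitter the
    beads dominate, while under heavy jitter all four features become
    comparably informative and the tip's long lever arm is kept.

    Raises
    ------
    DegenerateConfigurationError
        If no P3P candidate reprojects the pin tip inside the gate.
    """
    if tip_weight is None:
        cov = max(det.covariance_px2, 0.0)
        tip_weight = (cov + 0.1**2) / (cov + 0.35**2)
    f = _bearings(carm, det.beads)
    candidates = _p3p_grunert(f, fid.bead_centers)
    if not candidates:
        raise DegenerateConfigurationError("P3P yielded no feasible candidate")
    gated = []
    for Q in candidates:
        pose = _absolute_orientation(fid.bead_centers, Q)
        tip_cam = pose.apply(fid.pin_tip)
        if tip_cam[2] <= 0:
            continue
        uv = project_points(carm, pose, fid.pin_tip, apply_dist=False)
        err = float(np.linalg.norm(uv - det.pin_tip))
        if err <= gate_px:
            gated.append(pose)
    if not gated:
        raise DegenerateConfigurationError(
            f"no P3P candidate reprojects the pin tip within {gate_px} px"
        )
    best = None
    for pose0 in gated:
        pose = _refine_pose(pose0, fid, det, carm, tip_weight)
        uv = project_points(carm, pose, fid.points, apply_dist=False)
        res = np.linalg.norm(uv - det.points, axis=1)
        rms = float(np.sqrt((res**2).mean()))
        if best is None or rms < best[0]:
            best = (rms, pose, res)
    rms, pose, res = best
    return ImagePose(pose=pose, rms_reprojection=rms, per_point_residuals=res)
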