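"""2D contours: spline representation, silhouette extraction, segmentation.

The registration cost compares the projected outline (occluding contour)
of the fragment mesh with a contour segmented from the fluoroscopic image.
Segmented contours are represented as periodic cubic smoothing splines
parameterised by normalised arc length, with fast closest-point queries
backed by a dense polyline and a KD-tree.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import shapely
from scipy import ndimage
from scipy.interpolate import splev, splprep
from scipy.spatial import cKDTree

from .errors import MeshError, ProjectionError, SegmentationError
from .geometry import CArmModel, RigidTransform

__all__ = ["Contour2D", "extract_silhouette", "segment_contour"]


class Contour2D:
    """Ordered 2D contour with a smoothing-spline representation.

    Parameters
    ----------
    points : (n, 2) array
        Ordered contour points in px (n >= 8).
    closed : bool
        Whether the contour is a closed loop (periodic spline).
    smoothing : float
        Per-point RMS smoothing allowance in px (spline deviates from the
        input points by at most ~this much; bounded at 0.5 px at the knots
        for clean input).
    """

    def __init__(self, points, closed: bool = True, smoothing: float = 0.25):
        pts = np.asarray(points, float).reshape(-1, 2)
        if len(pts) < 8:
            raise SegmentationError(f"a contour needs >= 8 points, got {len(pts)}")
        if closed and np.linalg.norm(pts[0] - pts[-1]) < 1e-9:
            pts = pts[:-1]
        self.points = pts
        self.closed = bool(closed)
        self.smoothing = float(smoothing)
        self._build_spline()

    def _build_spline(self):
        pts = self.points
        if self.closed:
            wrap = np.vstack([pts, pts[:1]])
        else:
            wrap = pts
        seg = np.linalg.norm(np.diff(wrap, axis=0), axis=1)
        u = np.concatenate([[0.0], np.cumsum(seg)])
        total = u[-1]
        if total <= 0:
            raise SegmentationError("degenerate contour (zero length)")
        u = u / total
        s = len(pts) * self.smoothing**2
        self.tck, _ = splprep(
            [wrap[:, 0], wrap[:, 1]], u=u, s=s, per=1 if self.closed else 0, k=3
        )
        self.length_px = float(total)
        self._u = u[:-1] if self.closed else u
        # dense polyline for closest-point queries
        n_dense = max(512, 4 * len(pts))
        td = np.linspace(0.0, 1.0, n_dense, endpoint=not self.closed)
        xd, yd = splev(td, self.tck)
        dxd, dyd = splev(td, self.tck, der=1)
        tangent = np.stack([dxd, dyd], axis=1)
        tangent /= np.linalg.norm(tangent, axis=1)[:, None]
        self._dense = np.stack([xd, yd], axis=1)
        self._dense_normal = np.stack([-tangent[:, 1], tangent[:, 0]], axis=1)
        self._tree = cKDTree(self._dense)
        # dense samples bridging a dropped (occluded) span of the input points
        # are marked unsupported so matches against them can be discarded;
        # the margin is tight because the spline already bends away from the
        # true edge within a few px of a gap
        spacing = np.median(seg) if len(seg) else 1.0
        d_support, _ = cKDTree(pts).query(self._dense)
        self._dense_supported = d_support < max(1.2 * spacing, 2.0)

    def evaluate(self, t) -> np.ndarray:
        """Spline position at normalised arc-length parameter(s) t in [0, 1]."""
        x, y = splev(np.asarray(t, float), self.tck)
        return np.stack([np.atleast_1d(x), np.atleast_1d(y)], axis=1)

    def normals(self, t) -> np.ndarray:
        """Unit normals (left of travel direction) at parameter(s) t."""
        dx, dy = splev(np.asarray(t, float), self.tck, der=1)
        tang = np.stack([np.atleast_1d(dx), np.atleast_1d(dy)], axis=1)
        tang /= np.linalg.norm(tang, axis=1)[:, None]
        return np.stack([-tang[:, 1], tang[:, 0]], axis=1)

    def resample(self, n: int) -> np.ndarray:
        """n points evenly spaced in normalised arc length."""
        t = np.linspace(0.0, 1.0, n, endpoint=not self.closed)
        return self.evaluate(t)

    def closest_points(
        self, query
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """For each query point: (closest point, signed distance, normal, supported).

        The sign is along the stored contour normal at the closest dense
        sample (positive on the normal side).  ``supported`` is False where
        the closest point lies on a span that merely bridges dropped
        (occluded) input samples.
        """
        q = np.atleast_2d(np.asarray(query, float))
        _, idx = self._tree.query(q)
        cp = self._dense[idx]
        nrm = self._dense_normal[idx]
        d = ((q - cp) * nrm).sum(axis=1)
        return cp, d, nrm, self._dense_supported[idx]

    def knot_deviation(self) -> float:
        """Max spline-vs-input deviation at the knots (smoothing bound check)."""
        fit = self.evaluate(self._u)
        return float(np.linalg.norm(fit - self.points, axis=1).max())


def _project_mesh_vertices(
    vertices: np.ndarray, carm: CArmModel, cam_from_model: RigidTransform
) -> tuple[np.ndarray, np.ndarray]:
    cam = cam_from_model.apply(vertices)
    if (cam[:, 2] <= 0).any():
        raise ProjectionError("mesh has vertices at or behind the X-ray source")
    uv = cam[:, :2] * (carm.sid / cam[:, 2])[:, None] / carm.pixel_size + np.asarray(
        carm.principal_point
    )
    return uv, cam


def extract_silhouette(
    mesh,
    carm: CArmModel,
    camera_pose: RigidTransform,
    pose_guess: RigidTransform,
    n_points: int = 400,
) -> Contour2D:
    """Occluding contour of a mesh under the pinhole model.

    Projects every triangle, forms the exact union of the projected
    triangles (vector geometry), and returns its outer boundary as an
    ordered closed :class:`Contour2D` resampled to ``n_points``.

    ``camera_pose`` maps world -> camera; ``pose_guess`` maps the mesh
    model frame -> world.
    """
    faces = np.asarray(mesh.faces)
    n_edges = len(mesh.edges_unique)
    n_interior = len(mesh.face_adjacency_edges)
    if n_edges and (n_edges - n_interior) / n_edges > 0.02:
        raise MeshError("mesh is too open (boundary edges exceed 2% of edges)")
    uv, _ = _project_mesh_vertices(
        np.asarray(mesh.vertices, float), carm, camera_pose @ pose_guess
    )
    tris = uv[faces]  # (F, 3, 2)
    polys = shapely.polygons(tris)
    polys = shapely.make_valid(polys)
    union = shapely.union_all(polys)
    if union.geom_type == "MultiPolygon":
        union = max(union.geoms, key=lambda g: g.area)
    if union.geom_type != "Polygon" or union.is_empty:
        raise ProjectionError("mesh projection produced no silhouette area")
    ring = union.exterior
    t = np.linspace(0.0, ring.length, n_points, endpoint=False)
    pts = np.asarray(
        shapely.get_coordinates(shapely.line_interpolate_point(ring, t))
    )
    return Contour2D(pts, closed=True, smoothing=0.05)


def segment_contour(
    image, init_contour: Contour2D, params: dict | None = None
) -> Contour2D:
    """Refine an initial contour to the nearest strong image edge.

    Each sample of ``init_contour`` is moved along its normal to the
    intensity-gradient-magnitude peak inside a search window (default
    +/-15 px, 0.5 px steps, cubic image interpolation, sub-pixel quadratic
    peak refinement).  Samples with no gradient above the threshold (e.g.
    occluded by overlapping structures) are dropped; if more than the
    allowed fraction is dropped the segmentation fails.

    Raises
    ------
    SegmentationError
        If more than ``max_occluded_fraction`` (default 0.6) of the samples
        found no usable edge.
    """
    p = {
        "window_px": 15.0,
        "step_px": 0.5,
        "n_samples": None,  # default: one per init contour point
        "grad_threshold_frac": 0.05,  # of the image dynamic range, per px
        "max_occluded_fraction": 0.6,
        "smoothing": 0.25,
        "exclusion_polygons": (),  # shapely polygons; samples inside are dropped
    }
    if params:
        p.update(params)
    img = np.asarray(image, float)
    dyn = img.max() - img.min()
    thr = p["grad_threshold_frac"] * dyn  # per px

    n = p["n_samples"] or len(init_contour.points)
    t = np.linspace(0.0, 1.0, n, endpoint=not init_contour.closed)
    base = init_contour.evaluate(t)
    normals = init_contour.normals(t)

    steps = np.arange(-p["window_px"], p["window_px"] + 1e-9, p["step_px"])
    # sample image along each normal: (n, m)
    pts = base[:, None, :] + steps[None, :, None] * normals[:, None, :]
    vals = ndimage.map_coordinates(
        img, [pts[..., 1].ravel(), pts[..., 0].ravel()], order=3, mode="nearest"
    ).reshape(n, len(steps))
    grad = np.abs(np.gradient(vals, p["step_px"], axis=1))

    k = np.argmax(grad, axis=1)
    peak = grad[np.arange(n), k]
    ok = peak >= thr
    # sub-pixel quadratic refinement of the peak position
    k_c = np.clip(k, 1, len(steps) - 2)
    g0, g1, g2 = (
        grad[np.arange(n), k_c - 1],
        grad[np.arange(n), k_c],
        grad[np.arange(n), k_c + 1],
    )
    denom = g0 - 2 * g1 + g2
    delta = np.where(np.abs(denom) > 1e-12, 0.5 * (g0 - g2) / denom, 0.0)
    delta = np.clip(delta, -1.0, 1.0)
    offset = steps[k_c] + delta * p["step_px"]
    new_pts = base + offset[:, None] * normals

    # border samples cannot be localised
    h, w = img.shape
    inside = (
        (new_pts[:, 0] > 5)
        & (new_pts[:, 0] < w - 6)
        & (new_pts[:, 1] > 5)
        & (new_pts[:, 1] < h - 6)
    )
    ok &= inside
    if len(p["exclusion_polygons"]):
        pts_geom = shapely.points(new_pts)
        for poly in p["exclusion_polygons"]:
            ok &= ~shapely.contains(poly, pts_geom)

    occluded_fraction = 1.0 - ok.mean()
    if occluded_fraction > p["max_occluded_fraction"]:
        raise SegmentationError(
            f"{occluded_fraction:.0%} of contour samples occluded or off-image "
            f"(limit {p['max_occluded_fraction']:.0%}); view unusable"
        )
    return Contour2D(new_pts[ok], closed=init_contour.closed, smoothing=p["smoothing"])
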