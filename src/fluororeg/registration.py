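"""Model-to-image contour registration.

Given two posed fluoroscopic views (AP and LAT) with segmented fragment
contours, estimate the 6-DOF pose of the CT-derived fragment mesh that
minimises, summed over the views, the mean squared closest-point distance
(px) between the projected mesh outline and the segmented contour's
spline:

    C(theta) = sum_views mean_i d( silhouette_i(theta), spline_view )^2

The optimisation alternates closest-point correspondence updates with a
damped Gauss-Newton step over the 6 pose parameters (rotation about the
fragment centroid + translation), with Huber down-weighting of outlier
correspondences.  For efficiency the outline is sampled exactly on the
projected occluding edges of the mesh (facet front/back sign flips,
filtered by a point-in-projection coverage test) rather than by
rasterisation; the sampled points carry their generating 3D surface
points, giving a first-order analytic Jacobian (the standard
fixed-contour-generator approximation).

:class:`ContourRegistration` is the model object; :meth:`fit` returns a
:class:`RegistrationResult`.  :func:`coarse_align` provides a seeded
randomised stand-in for the surgeon's manual coarse alignment, and
:func:`pin_to_fragment` forms the pin-to-fragment transform that stays
constant for the rest of the operation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .contours import Contour2D
from .errors import ConvergenceError, ProjectionError
from .fiducial import ImagePose
from .geometry import CArmModel, RigidTransform

__all__ = [
    "ContourRegistration",
    "RegistrationResult",
    "SilhouetteSampler",
    "coarse_align",
    "pin_to_fragment",
]


class SilhouetteSampler:
    """Exact occluding-contour point sampler for one mesh.

    Precomputes the mesh connectivity; per pose, finds the edges whose two
    adjacent facets face opposite ways relative to the source, samples
    their projections at roughly ``spacing_px``, and discards samples
    covered by the projection of any other facet (such samples lie on
    interior folds, not the outer outline — for a closed surface every
    interior point is covered by the far side of the solid).
    """

    def __init__(self, mesh, carm: CArmModel):
        self.carm = carm
        self.vertices = np.asarray(mesh.vertices, float)
        self.faces = np.asarray(mesh.faces, int)
        self.adj_faces = np.asarray(mesh.face_adjacency, int)  # (E, 2)
        self.adj_edges = np.asarray(mesh.face_adjacency_edges, int)  # (E, 2)
        self.centroid = self.vertices.mean(axis=0)

    def sample(
        self,
        cam_from_model: RigidTransform,
        spacing_px: float = 4.0,
        n_samples: int | None = None,
    ) -> tuple[np.ndarray, np.ndarray]:
        """Sample the outline: returns (points_px (n, 2), points_cam (n, 3))."""
        carm = self.carm
        cam = cam_from_model.apply(self.vertices)
        z = cam[:, 2]
        if (z <= 0).any():
            raise ProjectionError("mesh has vertices at or behind the X-ray source")
        uv = cam[:, :2] * (carm.sid / z)[:, None] / carm.pixel_size + np.asarray(
            carm.principal_point
        )

        tri = cam[self.faces]
        n = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
        # perspective facing: sign of normal . view-ray (source at origin)
        facing = np.einsum("ij,ij->i", n, tri[:, 0]) < 0.0
        flip = facing[self.adj_faces[:, 0]] != facing[self.adj_faces[:, 1]]
        edges = self.adj_edges[flip]
        if len(edges) == 0:
            raise ProjectionError("no silhouette edges (degenerate projection)")

        a2, b2 = uv[edges[:, 0]], uv[edges[:, 1]]
        a3, b3 = cam[edges[:, 0]], cam[edges[:, 1]]
        lengths = np.linalg.norm(b2 - a2, axis=1)
        counts = np.maximum(1, np.ceil(lengths / spacing_px).astype(int))
        reps = np.repeat(np.arange(len(edges)), counts)
        frac = np.concatenate(
            [(np.arange(c) + 0.5) / c for c in counts]
        )
        p2 = a2[reps] + frac[:, None] * (b2 - a2)[reps]
        p3 = a3[reps] + frac[:, None] * (b3 - a3)[reps]
        excl = self.adj_faces[flip][reps]  # faces adjacent to each sample's edge

        keep = ~self._covered(p2, uv, excl)
        p2, p3 = p2[keep], p3[keep]
        if len(p2) == 0:
            raise ProjectionError("silhouette coverage test removed all samples")
        if n_samples is not None and len(p2) > n_samples:
            ctr = p2.mean(axis=0)
            order = np.argsort(np.arctan2(p2[:, 1] - ctr[1], p2[:, 0] - ctr[0]))
            sel = order[
                np.round(np.linspace(0, len(order) - 1, n_samples)).astype(int)
            ]
            p2, p3 = p2[sel], p3[sel]
        return p2, p3

    def _covered(self, pts: np.ndarray, uv: np.ndarray, excl: np.ndarray) -> np.ndarray:
        """True where a point lies strictly inside some non-adjacent facet."""
        tri = uv[self.faces]  # (F, 3, 2)
        a = tri[:, 0]
        e1 = tri[:, 1] - a
        e2 = tri[:, 2] - a
        det = e1[:, 0] * e2[:, 1] - e1[:, 1] * e2[:, 0]
        ok = np.abs(det) > 1e-9
        inv_det = np.where(ok, det, 1.0)
        d = pts[:, None, :] - a[None, :, :]  # (N, F, 2)
        l1 = (d[..., 0] * e2[None, :, 1] - d[..., 1] * e2[None, :, 0]) / inv_det
        l2 = (e1[None, :, 0] * d[..., 1] - e1[None, :, 1] * d[..., 0]) / inv_det
        eps = 1e-3
        inside = (l1 > eps) & (l2 > eps) & (l1 + l2 < 1.0 - eps) & ok[None, :]
        ar = np.arange(len(pts))
        inside[ar, excl[:, 0]] = False
        inside[ar, excl[:, 1]] = False
        return inside.any(axis=1)


@dataclass
class RegistrationResult:
    """Estimated fragment pose with convergence diagnostics.

    ``fragment_pose`` maps the fragment model frame into the world frame
    (the registration-tool/pin frame); ``pin_to_fragment`` is the derived
    pin-to-fragment transform that is treated as constant intra-operatively.
    """

    fragment_pose: RigidTransform
    final_cost: float  # px^2 (sum over views of mean squared distance)
    initial_cost: float
    iterations: int
    converged: bool
    per_view_rms: np.ndarray  # px
    pin_to_fragment: RigidTransform
    cost_trace: np.ndarray = field(default_factory=lambda: np.empty(0))

    def summary(self) -> str:
        views = " / ".join(f"{r:.3f}" for r in self.per_view_rms)
        return "\n".join(
            [
                "Contour registration",
                "=" * 46,
                f"converged            : {self.converged}",
                f"iterations           : {self.iterations}",
                f"cost (init -> final) : {self.initial_cost:.4f} -> {self.final_cost:.4f} px^2",
                f"per-view contour RMS : {views} px",
                f"fragment pose        : {self.fragment_pose!r}",
            ]
        )

    def to_dict(self) -> dict:
        return {
            "fragment_pose": self.fragment_pose.to_dict(),
            "final_cost": self.final_cost,
            "initial_cost": self.initial_cost,
            "iterations": self.iterations,
            "converged": self.converged,
            "per_view_rms": self.per_view_rms.tolist(),
            "pin_to_fragment": self.pin_to_fragment.to_dict(),
        }

    def save(self, path):
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def load(cls, path) -> "RegistrationResult":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    @classmethod
    def from_dict(cls, d: dict) -> "RegistrationResult":
        return cls(
            fragment_pose=RigidTransform.from_dict(d["fragment_pose"]),
            final_cost=float(d["final_cost"]),
            initial_cost=float(d["initial_cost"]),
            iterations=int(d["iterations"]),
            converged=bool(d["converged"]),
            per_view_rms=np.asarray(d["per_view_rms"], float),
            pin_to_fragment=RigidTransform.from_dict(d["pin_to_fragment"]),
        )


def _rotvec_matrix(w: np.ndarray) -> np.ndarray:
    from scipy.spatial.transform import Rotation

    return Rotation.from_rotvec(w).as_matrix()


class ContourRegistration:
    """Registration model: fragment mesh + segmented contours + view poses.

    Parameters
    ----------
    mesh : trimesh.Trimesh
        Fragment surface in its model (CT) frame, mm.
    contours : sequence of Contour2D
        One segmented contour per view (same order as ``image_poses``).
    image_poses : sequence of ImagePose or RigidTransform
        World (RT frame) -> camera transforms for each view.
    carm : CArmModel
    n_samples : int
        Outline samples per view per iteration (default 200).
    huber_px : float
        Huber scale for outlier down-weighting (default 3 px).
    """

    def __init__(
        self,
        mesh,
        contours,
        image_poses,
        carm: CArmModel,
        n_samples: int = 200,
        huber_px: float = 3.0,
    ):
        self.mesh = mesh
        self.contours: list[Contour2D] = list(contours)
        self.cam_poses: list[RigidTransform] = [
            p.pose if isinstance(p, ImagePose) else p for p in image_poses
        ]
        if len(self.contours) != len(self.cam_poses):
            raise ValueError("one contour per image pose required")
        self.carm = carm
        self.n_samples = int(n_samples)
        self.huber_px = float(huber_px)
        self.sampler = SilhouetteSampler(mesh, carm)

    # -- cost ---------------------------------------------------------
    def _view_terms(self, pose: RigidTransform, view: int, n_samples: int, spacing_px: float = 4.0):
        cam_pose = self.cam_poses[view]
        p2, p3 = self.sampler.sample(
            cam_pose @ pose, n_samples=n_samples, spacing_px=spacing_px
        )
        _, d, nrm, supported = self.contours[view].closest_points(p2)
        h, w = self.carm.image_shape
        inside = (
            (p2[:, 0] > 10) & (p2[:, 0] < w - 11) & (p2[:, 1] > 10) & (p2[:, 1] < h - 11)
        )
        keep = supported & inside
        return p2[keep], p3[keep], d[keep], nrm[keep]

    def cost(
        self,
        pose: RigidTransform,
        n_samples: int | None = None,
        spacing_px: float = 4.0,
    ) -> float:
        """Registration cost C(pose) in px^2 (sum of per-view mean squares)."""
        n = n_samples or self.n_samples
        total = 0.0
        for v in range(len(self.contours)):
            _, _, d, _ = self._view_terms(pose, v, n, spacing_px)
            if len(d) == 0:
                return np.inf
            w = self._huber_weights(d)
            total += float((w * d**2).mean())
        return total

    def _huber_weights(self, d: np.ndarray) -> np.ndarray:
        a = np.abs(d)
        return np.where(a <= self.huber_px, 1.0, self.huber_px / np.maximum(a, 1e-12))

    # -- fitting ------------------------------------------------------
    def fit(
        self,
        init: RigidTransform,
        pin_pose: RigidTransform | None = None,
        max_iter: int = 200,
        tol: float = 1e-8,
        max_stalls: int = 5,
        raise_on_max_iter: bool = True,
    ) -> RegistrationResult:
        """Damped Gauss-Newton minimisation from ``init``.

        Convergence is declared when the relative cost change falls below
        ``tol`` (or no damped step can further decrease the cost); a
        :class:`ConvergenceError` carrying the cost trace is raised if the
        iteration budget is exhausted while the cost is still improving.
        """
        pose = init
        pin_pose = pin_pose or RigidTransform.identity()
        lam = 1e-3
        cost = self.cost(pose)
        initial_cost = cost
        trace = [cost]
        converged = False
        stalls = 0
        it = 0
        for it in range(1, max_iter + 1):
            JTJ = np.zeros((6, 6))
            JTr = np.zeros(6)
            c_world = pose.apply(self.sampler.centroid)
            n_res = 0
            for v in range(len(self.contours)):
                p2, p3, d, nrm = self._view_terms(pose, v, self.n_samples)
                if len(d) == 0:
                    continue
                J = self._jacobian(v, p2, p3, nrm, pose, c_world)
                w = self._huber_weights(d) / len(d)  # per-view mean, as in cost()
                JTJ += (J * w[:, None]).T @ J
                JTr += (J * w[:, None]).T @ d
                n_res += len(d)
            if n_res == 0:
                raise ConvergenceError("no usable correspondences", trace=np.array(trace))

            improved = False
            for _ in range(10):
                H = JTJ + lam * np.diag(np.diag(JTJ) + 1e-12)
                try:
                    step = np.linalg.solve(H, -JTr)
                except np.linalg.LinAlgError:
                    lam *= 10
                    continue
                new_pose = self._apply_step(pose, step, c_world)
                try:
                    new_cost = self.cost(new_pose)
                except ProjectionError:
                    new_cost = np.inf
                if new_cost < cost:
                    rel = (cost - new_cost) / max(cost, 1e-300)
                    pose, cost = new_pose, new_cost
                    trace.append(cost)
                    lam = max(lam / 3.0, 1e-9)
                    improved = True
                    stalls = 0
                    if rel < tol:
                        converged = True
                    break
                lam *= 10
            if converged:
                break
            if not improved:
                stalls += 1
                if stalls >= max_stalls or lam > 1e8:
                    # no damped step decreases the cost: local minimum
                    converged = True
                    break
        else:
            if raise_on_max_iter:
                raise ConvergenceError(
                    f"registration still improving after {max_iter} iterations",
                    trace=np.array(trace),
                )

        per_view = []
        for v in range(len(self.contours)):
            _, _, d, _ = self._view_terms(pose, v, self.n_samples)
            per_view.append(float(np.sqrt((d**2).mean())) if len(d) else np.nan)
        return RegistrationResult(
            fragment_pose=pose,
            final_cost=cost,
            initial_cost=initial_cost,
            iterations=it,
            converged=converged,
            per_view_rms=np.asarray(per_view),
            pin_to_fragment=pin_to_fragment(pose, pin_pose),
            cost_trace=np.asarray(trace),
        )

    def _jacobian(self, view, p2, p3, nrm, pose, c_world):
        """d residual / d (omega, dt) under the material-point approximation."""
        carm = self.carm
        cam_pose = self.cam_poses[view]
        R_cam = cam_pose.rotation
        x, y, z = p3[:, 0], p3[:, 1], p3[:, 2]
        k = carm.sid / carm.pixel_size
        # du/dX_cam rows: (n, 2, 3)
        dP = np.zeros((len(p3), 2, 3))
        dP[:, 0, 0] = k / z
        dP[:, 0, 2] = -k * x / z**2
        dP[:, 1, 1] = k / z
        dP[:, 1, 2] = -k * y / z**2
        # world points of the samples
        Xw = cam_pose.inverse().apply(p3) - c_world
        # dX_cam/d omega = -R_cam [Xw - c]x ; dX_cam/d dt = R_cam
        skew = np.zeros((len(p3), 3, 3))
        skew[:, 0, 1] = -Xw[:, 2]
        skew[:, 0, 2] = Xw[:, 1]
        skew[:, 1, 0] = Xw[:, 2]
        skew[:, 1, 2] = -Xw[:, 0]
        skew[:, 2, 0] = -Xw[:, 1]
        skew[:, 2, 1] = Xw[:, 0]
        dXc_dw = -np.einsum("ab,nbc->nac", R_cam, skew)
        duv_dw = np.einsum("nab,nbc->nac", dP, dXc_dw)  # (n, 2, 3)
        duv_dt = np.einsum("nab,bc->nac", dP, R_cam)
        J = np.concatenate([duv_dw, duv_dt], axis=2)  # (n, 2, 6)
        # residual is the signed distance along the contour normal
        return np.einsum("na,nab->nb", nrm, J)

    @staticmethod
    def _apply_step(pose: RigidTransform, step: np.ndarray, c_world: np.ndarray):
        Rw = _rotvec_matrix(step[:3])
        R_new = Rw @ pose.rotation
        t_new = Rw @ (pose.translation - c_world) + c_world + step[3:]
        return RigidTransform(R_new, t_new, validate=False)


def pin_to_fragment(
    fragment_pose: RigidTransform, pin_pose: RigidTransform
) -> RigidTransform:
    """Pin-to-fragment transform: ``invert(pin_pose) o fragment_pose``.

    Both poses must be expressed in the same world frame.  In the usual
    registration world frame (the RT/pin frame itself) ``pin_pose`` is the
    identity and the result equals the fragment pose.
    """
    return pin_pose.inverse() @ fragment_pose


def coarse_align(
    mesh,
    contours,
    image_poses,
    carm: CArmModel,
    search_params: dict | None = None,
    seed: int = 0,
) -> RigidTransform:
    """Randomised stand-in for the surgeon's manual coarse alignment.

    Draws pose samples around an initial guess (by default: identity
    rotation, translation from triangulating the two contour centroids)
    within +/-``translation_mm`` and +/-``rotation_deg`` per axis, scores
    each by the registration cost, and returns the best.  The sample
    budget (default 200) is split into a wide stage and a refinement stage
    around the wide stage's best.  Deterministic given ``seed``.
    """
    p = {
        "n_samples": 200,
        "translation_mm": 15.0,
        "rotation_deg": 15.0,
        "init_pose": None,
        "score_samples": 100,
    }
    if search_params:
        p.update(search_params)
    model = ContourRegistration(mesh, contours, image_poses, carm)
    cam_poses = model.cam_poses

    rng = np.random.default_rng(seed)
    if p["init_pose"] is not None:
        center = p["init_pose"]
    else:
        # no orientation prior: pick the best of a set of global rotations
        # at the triangulated centroid before the local search
        target = _triangulate_centroid(contours, cam_poses, carm)
        mesh_c = np.asarray(mesh.vertices, float).mean(axis=0)
        from scipy.spatial.transform import Rotation

        best = None
        for k in range(60):
            R = (
                np.eye(3)
                if k == 0
                else Rotation.random(random_state=np.random.RandomState(seed * 997 + k)).as_matrix()
            )
            cand = RigidTransform(R, target - R @ mesh_c, validate=False)
            try:
                c = model.cost(cand, n_samples=p["score_samples"], spacing_px=8.0)
            except ProjectionError:
                continue
            if best is None or c < best[0]:
                best = (c, cand)
        center = best[1]

    def score(pose):
        try:
            # coarse scoring runs on a sparser outline sampling for speed
            return model.cost(pose, n_samples=p["score_samples"], spacing_px=8.0)
        except ProjectionError:
            return np.inf

    best_pose, best_cost = center, score(center)
    n1 = int(p["n_samples"] * 0.6)
    stages = [(n1, 1.0), (p["n_samples"] - n1, 1.0 / 3.0)]
    for n_stage, scale in stages:
        base = best_pose
        for _ in range(n_stage):
            if p["rotation_deg"] == 0 and p["translation_mm"] == 0:
                break
            w = rng.uniform(-1, 1, 3) * np.radians(p["rotation_deg"]) * scale
            dt = rng.uniform(-1, 1, 3) * p["translation_mm"] * scale
            c_world = base.apply(np.asarray(mesh.vertices, float).mean(axis=0))
            cand = ContourRegistration._apply_step(
                base, np.concatenate([w, dt]), c_world
            )
            c = score(cand)
            if c < best_cost:
                best_pose, best_cost = cand, c
    if p["rotation_deg"] == 0 and p["translation_mm"] == 0:
        return best_pose  # degenerate search box: the centre is the answer
    if p.get("polish_iter", 12) and best_cost < np.inf:
        # a few damped Gauss-Newton steps settle the sampled pose into its
        # basin, like the surgeon nudging the overlay until it sits
        try:
            best_pose = model.fit(
                best_pose,
                max_iter=int(p.get("polish_iter", 12)),
                tol=1e-4,
                raise_on_max_iter=False,
            ).fragment_pose
        except ConvergenceError:
            pass
    return best_pose


def _triangulate_centroid(contours, cam_poses, carm: CArmModel) -> np.ndarray:
    """World point nearest the back-projected rays of the contour centroids."""
    A = np.zeros((3, 3))
    b = np.zeros(3)
    for contour, cam_pose in zip(contours, cam_poses):
        c_px = contour.points.mean(axis=0)
        xy = (c_px - np.asarray(carm.principal_point)) * carm.pixel_size
        d_cam = np.array([xy[0], xy[1], carm.sid])
        d_cam /= np.linalg.norm(d_cam)
        inv = cam_pose.inverse()
        origin = inv.translation  # source position in world
        d_w = inv.rotation @ d_cam
        P = np.eye(3) - np.outer(d_w, d_w)
        A += P
        b += P @ origin
    return np.linalg.solve(A, b)
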