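"""Registration accuracy metrics and the intra-operative target-pose chain.

The headline accuracy metric is the surface target registration error
(sTRE): points are sampled area-uniformly on the *fracture surfaces* of a
fragment (those are the surfaces that must be matched when the fracture is
reduced), mapped through both the ground-truth pose and the estimated
pose, and the per-point Euclidean distances are summarised as mean +/- sd.

This module also provides the transform chain that converts a desired
fragment pose from image space into a robotic fracture manipulator (RFM)
target pose, and translational/rotational RMSE summaries for achieved
vs. desired reductions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import FluororegError, MeshError
from .geometry import RigidTransform

__all__ = [
    "FractureSurfaceSamples",
    "STREReport",
    "DesiredPose",
    "sample_fracture_surface",
    "compute_stre",
    "rfm_target_pose",
    "reduction_rmse",
]


@dataclass
class FractureSurfaceSamples:
    """Points sampled on labelled fracture-surface faces (model frame, mm)."""

    points: np.ndarray  # (n, 3)
    n: int
    seed: int


@dataclass
class STREReport:
    """Surface target registration error summary (mm)."""

    mean: float
    sd: float
    n: int
    per_point: np.ndarray

    @classmethod
    def from_distances(cls, d: np.ndarray) -> "STREReport":
        d = np.asarray(d, float)
        return cls(mean=float(d.mean()), sd=float(d.std(ddof=0)), n=len(d), per_point=d)

    def summary(self) -> str:
        return f"sTRE = {self.mean:.3f} +/- {self.sd:.3f} mm (n = {self.n})"

    def to_dict(self) -> dict:
        return {"mean": self.mean, "sd": self.sd, "n": self.n}


@dataclass
class DesiredPose:
    """A labelled pose (e.g. the planned reduced configuration of a fragment)."""

    pose: RigidTransform
    frame: str = ""


def sample_fracture_surface(mesh, fracture_faces, n: int, seed: int = 0) -> FractureSurfaceSamples:
    """Draw ``n`` points area-uniformly from the labelled fracture faces.

    Deterministic given ``seed``.  Raises :class:`MeshError` if the mesh
    has no labelled fracture faces.
    """
    faces = np.asarray(fracture_faces, int)
    if faces.size == 0:
        raise MeshError("mesh has no faces labelled as fracture surface")
    tri = np.asarray(mesh.vertices, float)[np.asarray(mesh.faces, int)[faces]]
    if n == 0:
        return FractureSurfaceSamples(points=np.empty((0, 3)), n=0, seed=seed)
    e1 = tri[:, 1] - tri[:, 0]
    e2 = tri[:, 2] - tri[:, 0]
    areas = 0.5 * np.linalg.norm(np.cross(e1, e2), axis=1)
    if areas.sum() <= 0:
        raise MeshError("labelled fracture faces have zero total area")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x57]))
    idx = rng.choice(len(faces), size=n, p=areas / areas.sum())
    r1 = np.sqrt(rng.random(n))
    r2 = rng.random(n)
    # area-uniform barycentric sampling
    pts = (
        tri[idx, 0] * (1 - r1)[:, None]
        + tri[idx, 1] * (r1 * (1 - r2))[:, None]
        + tri[idx, 2] * (r1 * r2)[:, None]
    )
    return FractureSurfaceSamples(points=pts, n=n, seed=seed)


def compute_stre(
    samples: FractureSurfaceSamples,
    pose_true: RigidTransform,
    pose_est: RigidTransform,
) -> STREReport:
    """Distance between matching fracture-surface points under the two poses."""
    if samples.n == 0:
        raise FluororegError("cannot compute sTRE from an empty sample set")
    d = np.linalg.norm(
        pose_true.apply(samples.points) - pose_est.apply(samples.points), axis=1
    )
    return STREReport.from_distances(d)


def rfm_target_pose(
    rfm_to_pin: RigidTransform,
    img_to_fragment: RigidTransform,
    desired: DesiredPose,
) -> DesiredPose:
    """Desired manipulator pose: ``rfm_to_pin x img_to_fragment x desired``.

    Composition order follows the intra-operative chain: the planned
    fragment pose (image space) is mapped through the image-to-task-space
    correspondence of that fragment and then through the tracked
    manipulator-to-pin transform.
    """
    return DesiredPose(
        pose=rfm_to_pin @ img_to_fragment @ desired.pose,
        frame="RFM",
    )


def reduction_rmse(
    achieved_poses, desired_poses, probe_points
) -> tuple[float, float]:
    """(translational mm, rotational deg) RMSE of achieved vs desired poses.

    Translational error per pair is the RMS displacement of ``probe_points``
    (model-frame test points, e.g. fracture-surface samples); rotational
    error is the geodesic angle of relative rotation.
    """
    achieved = list(achieved_poses)
    desired = list(desired_poses)
    if len(achieved) != len(desired):
        raise FluororegError("achieved and desired pose lists differ in length")
    pts = np.atleast_2d(np.asarray(probe_points, float))
    dts, drs = [], []
    for a, d in zip(achieved, desired):
        a = a.pose if isinstance(a, DesiredPose) else a
        d = d.pose if isinstance(d, DesiredPose) else d
        disp = a.apply(pts) - d.apply(pts)
        dts.append(np.sqrt((np.linalg.norm(disp, axis=1) ** 2).mean()))
        drs.append((a.inverse() @ d).rotation_angle_deg())
    dt = float(np.sqrt(np.mean(np.square(dts))))
    dr = float(np.sqrt(np.mean(np.square(drs))))
    return dt, dr
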