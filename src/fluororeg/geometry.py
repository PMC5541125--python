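"""Rigid transforms and the C-arm imaging model.

The C-arm is modelled as a pinhole camera: the X-ray source sits at the
origin of the camera frame, the optical axis is +z, and the detector
(image-intensifier input) plane lies at ``z = SID`` (source-to-image
distance, which plays the role of the focal length).  Image coordinates are
``(u, v)`` in pixels, origin at the top-left corner, with the principal
point at the detector centre.  All lengths are in mm, image coordinates in
px, angles in degrees at the API surface.

Camera poses map *world* coordinates into this camera frame; a fragment or
fiducial pose maps the object's model frame into the world frame.  The
image-intensifier pincushion distortion is represented, on the synthesis
side only, as an even-power radial polynomial in pixel coordinates about a
distortion centre; the calibration module recovers a correction for it
without knowledge of this functional form.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np

from .errors import ProjectionError, ValidationError

__all__ = [
    "RigidTransform",
    "RadialDistortion",
    "CArmModel",
    "compose",
    "invert",
    "project_points",
    "apply_distortion",
]

_ORTHO_TOL = 1e-9


class RigidTransform:
    """A proper rigid transform (rotation + translation) in 3D.

    Parameters
    ----------
    rotation : (3, 3) array_like
        Orthonormal matrix with determinant +1.
    translation : (3,) array_like
        Translation in mm.
    """

    __slots__ = ("rotation", "translation")

    def __init__(self, rotation, translation, *, validate=True, tol=1e-6):
        R = np.asarray(rotation, dtype=float).reshape(3, 3)
        t = np.asarray(translation, dtype=float).reshape(3)
        if validate:
            err_o = np.abs(R.T @ R - np.eye(3)).max()
            err_d = abs(np.linalg.det(R) - 1.0)
            if err_o > tol or err_d > tol:
                raise ValidationError(
                    f"rotation not orthonormal/proper (orth err {err_o:.2e}, "
                    f"det err {err_d:.2e}, tol {tol:.0e})"
                )
        self.rotation = R
        self.translation = t

    # -- constructors -------------------------------------------------
    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3), validate=False)

    @classmethod
    def from_matrix(cls, m, **kw) -> "RigidTransform":
        m = np.asarray(m, dtype=float)
        if m.shape != (4, 4):
            raise ValidationError(f"expected 4x4 matrix, got {m.shape}")
        if np.abs(m[3] - [0, 0, 0, 1]).max() > 1e-9:
            raise ValidationError("bottom row of homogeneous matrix must be [0,0,0,1]")
        return cls(m[:3, :3], m[:3, 3], **kw)

    @classmethod
    def from_rotvec_deg(cls, rotvec_deg, translation=(0.0, 0.0, 0.0)) -> "RigidTransform":
        from scipy.spatial.transform import Rotation

        R = Rotation.from_rotvec(np.asarray(rotvec_deg, float), degrees=True).as_matrix()
        return cls(R, translation, validate=False)

    @classmethod
    def random(cls, rng, max_translation=100.0, max_angle_deg=180.0) -> "RigidTransform":
        """Uniform random rotation (scaled) + uniform translation in a cube."""
        from scipy.spatial.transform import Rotation

        axis = rng.normal(size=3)
        axis /= np.linalg.norm(axis)
        angle = rng.uniform(-max_angle_deg, max_angle_deg)
        R = Rotation.from_rotvec(axis * angle, degrees=True).as_matrix()
        t = rng.uniform(-max_translation, max_translation, size=3)
        return cls(R, t, validate=False)

    # -- algebra ------------------------------------------------------
    @property
    def matrix(self) -> np.ndarray:
        m = np.eye(4)
        m[:3, :3] = self.rotation
        m[:3, 3] = self.translation
        return m

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return ``self o other`` (apply *other* first)."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
            validate=False,
        )

    def __matmul__(self, other):
        if isinstance(other, RigidTransform):
            return self.compose(other)
        return NotImplemented

    def inverse(self) -> "RigidTransform":
        Rt = self.rotation.T
        return RigidTransform(Rt, -Rt @ self.translation, validate=False)

    def apply(self, points) -> np.ndarray:
        """Transform an (n, 3) array (or a single 3-vector) of points."""
        p = np.asarray(points, dtype=float)
        single = p.ndim == 1
        p = np.atleast_2d(p)
        out = p @ self.rotation.T + self.translation
        return out[0] if single else out

    # -- diagnostics --------------------------------------------------
    def rotation_angle_deg(self) -> float:
        """Geodesic rotation angle of this transform, in degrees."""
        c = (np.trace(self.rotation) - 1.0) / 2.0
        return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))

    def distance_to(self, other: "RigidTransform") -> tuple[float, float]:
        """(translation mm, geodesic rotation deg) between two transforms."""
        delta = self.inverse() @ other
        return float(np.linalg.norm(delta.translation)), delta.rotation_angle_deg()

    def allclose(self, other: "RigidTransform", atol=1e-9) -> bool:
        return bool(np.allclose(self.matrix, other.matrix, atol=atol))

    # -- serialization ------------------------------------------------
    def to_dict(self) -> dict:
        return {"matrix": [[float(x) for x in row] for row in self.matrix]}

    @classmethod
    def from_dict(cls, d: dict, tol=1e-6) -> "RigidTransform":
        return cls.from_matrix(np.asarray(d["matrix"], float), validate=True, tol=tol)

    def __repr__(self):
        t = np.array2string(self.translation, precision=3, suppress_small=True)
        return f"RigidTransform(angle={self.rotation_angle_deg():.3f} deg, t={t} mm)"


def compose(a: RigidTransform, b: RigidTransform) -> RigidTransform:
    """Composition ``a o b``: the result maps x to a(b(x))."""
    return a.compose(b)


def invert(t: RigidTransform) -> RigidTransform:
    """Inverse transform: ``compose(t, invert(t))`` is the identity."""
    return t.inverse()


@dataclass(frozen=True)
class RadialDistortion:
    """Even-power radial distortion about a centre, in pixel units.

    A point at radius ``r`` px from ``center`` maps to
    ``r' = r * (1 + k1 r^2 + k2 r^4 + ...)``; positive coefficients stretch
    the periphery (pincushion).  The identity mapping corresponds to all
    coefficients zero.
    """

    coefficients: tuple  # k1 (px^-2), k2 (px^-4), ...
    center: tuple  # (u, v) px

    def __post_init__(self):
        object.__setattr__(self, "coefficients", tuple(float(k) for k in self.coefficients))
        object.__setattr__(self, "center", tuple(float(c) for c in self.center))

    def _scale(self, r2: np.ndarray) -> np.ndarray:
        s = np.ones_like(r2)
        p = np.ones_like(r2)
        for k in self.coefficients:
            p = p * r2
            s = s + k * p
        return s

    def apply(self, points_px) -> np.ndarray:
        p = np.atleast_2d(np.asarray(points_px, float))
        d = p - self.center
        r2 = (d**2).sum(axis=1)
        out = self.center + d * self._scale(r2)[:, None]
        return out if np.asarray(points_px).ndim > 1 else out[0]

    def unapply(self, points_px, tol=1e-10, max_iter=50) -> np.ndarray:
        """Numerically invert :meth:`apply` (Newton iteration on the radius)."""
        p = np.atleast_2d(np.asarray(points_px, float))
        d = p - self.center
        r_obs = np.sqrt((d**2).sum(axis=1))
        r = r_obs.copy()
        for _ in range(max_iter):
            s = self._scale(r**2)
            # d/dr [r * s(r^2)]
            ds = np.zeros_like(r)
            p2 = np.ones_like(r)
            for i, k in enumerate(self.coefficients, start=1):
                p2 = p2 * r**2
                ds = ds + k * (2 * i) * p2 / np.where(r > 0, r, 1.0) * r
            f = r * s - r_obs
            fp = s + ds
            step = f / fp
            r = r - step
            if np.abs(step).max() < tol:
                break
        with np.errstate(invalid="ignore", divide="ignore"):
            scale = np.where(r_obs > 0, r / r_obs, 1.0)
        out = self.center + d * scale[:, None]
        return out if np.asarray(points_px).ndim > 1 else out[0]


def apply_distortion(d: RadialDistortion, points_px) -> np.ndarray:
    """Apply the synthesis-side radial distortion model to pixel points."""
    return d.apply(points_px)


@dataclass(frozen=True)
class CArmModel:
    """C-arm fluoroscope intrinsics.

    Defaults match a mobile C-arm with a 230-mm image intensifier, SID of
    980 mm and a 0.224 mm detector pixel pitch.
    """

    sid: float = 980.0  # mm, source-to-image distance (focal length)
    pixel_size: float = 0.224  # mm / px
    detector_diameter: float = 230.0  # mm
    principal_point: tuple = (515.0, 515.0)  # (u, v) px
    image_shape: tuple = (1030, 1030)  # (rows, cols) px
    distortion: RadialDistortion | None = None  # synthesis only

    def __post_init__(self):
        if self.sid <= 0 or self.pixel_size <= 0:
            raise ValidationError("sid and pixel_size must be positive")
        if self.detector_diameter / self.pixel_size > max(self.image_shape) + 1e-9:
            raise ValidationError("detector does not fit in image_shape at this pixel size")

    # -- serialization ------------------------------------------------
    def to_dict(self) -> dict:
        d = {
            "sid": self.sid,
            "pixel_size": self.pixel_size,
            "detector_diameter": self.detector_diameter,
            "principal_point": list(self.principal_point),
            "image_shape": list(self.image_shape),
        }
        if self.distortion is not None:
            d["distortion"] = {
                "coefficients": list(self.distortion.coefficients),
                "center": list(self.distortion.center),
            }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CArmModel":
        dist = None
        if d.get("distortion"):
            dist = RadialDistortion(
                coefficients=tuple(d["distortion"]["coefficients"]),
                center=tuple(d["distortion"]["center"]),
            )
        return cls(
            sid=float(d["sid"]),
            pixel_size=float(d["pixel_size"]),
            detector_diameter=float(d["detector_diameter"]),
            principal_point=tuple(d["principal_point"]),
            image_shape=tuple(int(v) for v in d["image_shape"]),
            distortion=dist,
        )

    def replace(self, **kw) -> "CArmModel":
        return dataclasses.replace(self, **kw)

    def save(self, path):
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def load(cls, path) -> "CArmModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def project_points(
    carm: CArmModel, camera_pose: RigidTransform, points3d, *, apply_dist: bool = True
) -> np.ndarray:
    """Project world points through the pinhole C-arm model.

    ``camera_pose`` maps world to camera coordinates.  With the source at
    the camera origin and the detector at ``z = sid``:

        u = (x * sid / z) / pixel_size + principal_point_u   (likewise v)

    The synthesis-side distortion, if configured on ``carm``, is applied to
    the resulting pixel coordinates (disable with ``apply_dist=False``).

    Raises
    ------
    ProjectionError
        If any point has z <= 0 in the camera frame (at or behind the source).
    """
    pts = np.atleast_2d(np.asarray(points3d, float))
    cam = camera_pose.apply(pts)
    z = cam[:, 2]
    bad = np.nonzero(z <= 0)[0]
    if bad.size:
        raise ProjectionError(
            f"{bad.size} point(s) at or behind the X-ray source (indices {bad[:5].tolist()}...)"
        )
    uv = (cam[:, :2] * (carm.sid / z)[:, None]) / carm.pixel_size + np.asarray(
        carm.principal_point
    )
    if apply_dist and carm.distortion is not None:
        uv = carm.distortion.apply(uv)
    single = np.asarray(points3d).ndim == 1
    return uv[0] if single else uv
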