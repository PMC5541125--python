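"""File formats: STL meshes with fracture-surface labels, transforms, images.

STL (the format CT segmentation pipelines export) carries no face
attributes, so fracture-surface labels travel in a JSON sidecar named
``<mesh>.labels.json`` holding the fracture-surface face indices.
Transforms are stored as row-major 4x4 homogeneous matrices in JSON with
full double precision and are validated (orthonormality, unit bottom row)
on read.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import trimesh

from .errors import MeshError, ValidationError
from .geometry import RigidTransform

__all__ = [
    "read_mesh",
    "write_mesh",
    "read_transform",
    "write_transform",
    "read_image",
    "write_image",
]


def _sidecar(path) -> Path:
    p = Path(path)
    return p.with_suffix(p.suffix + ".labels.json")


def read_mesh(path) -> tuple[trimesh.Trimesh, np.ndarray | None]:
    """Read a binary or ASCII STL mesh (mm) plus optional fracture labels.

    Returns ``(mesh, fracture_faces)`` where ``fracture_faces`` is an int
    array of face indices or ``None`` if no sidecar exists.

    Raises
    ------
    MeshError
        On a malformed or truncated STL file.
    """
    try:
        mesh = trimesh.load_mesh(str(path), file_type="stl", process=False)
    except Exception as ex:  # trimesh raises various concrete types
        raise MeshError(f"cannot parse STL {path}: {ex}") from ex
    if not isinstance(mesh, trimesh.Trimesh) or len(mesh.faces) == 0:
        raise MeshError(f"{path} contains no triangles")
    # STL stores a triangle soup; weld identical vertices so edge/facet
    # adjacency (needed for silhouette extraction) exists again
    mesh.merge_vertices()
    labels = None
    sc = _sidecar(path)
    if sc.exists():
        with open(sc) as fh:
            data = json.load(fh)
        labels = np.asarray(data["fracture_faces"], dtype=int)
        if labels.size and (labels.min() < 0 or labels.max() >= len(mesh.faces)):
            raise ValidationError(f"{sc} labels out of range for {len(mesh.faces)} faces")
    return mesh, labels


def write_mesh(path, mesh: trimesh.Trimesh, fracture_faces=None):
    """Write a binary STL (+ label sidecar if ``fracture_faces`` given)."""
    mesh.export(str(path), file_type="stl")
    if fracture_faces is not None:
        with open(_sidecar(path), "w") as fh:
            json.dump(
                {"fracture_faces": np.asarray(fracture_faces, int).tolist()}, fh
            )


def write_transform(path, t: RigidTransform):
    """Serialise a transform as a row-major 4x4 JSON matrix (lossless)."""
    with open(path, "w") as fh:
        json.dump(t.to_dict(), fh, indent=2)


def read_transform(path, tol: float = 1e-6) -> RigidTransform:
    """Read and validate a transform (orthonormality within ``tol``).

    Raises
    ------
    ValidationError
        If the stored matrix is not a proper rigid transform.
    """
    with open(path) as fh:
        d = json.load(fh)
    return RigidTransform.from_dict(d, tol=tol)


def write_image(path, image: np.ndarray):
    """Write a float image as 16-bit TIFF/PNG (clipped to [0, 1] full scale)."""
    import imageio.v3 as iio

    arr = np.clip(np.asarray(image, float), 0.0, 1.0)
    iio.imwrite(str(path), (arr * 65535).astype(np.uint16))


def read_image(path) -> np.ndarray:
    """Read an 8/16-bit grayscale image to float in [0, 1]."""
    import imageio.v3 as iio

    arr = np.asarray(iio.imread(str(path)))
    if arr.ndim == 3:
        arr = arr[..., 0]
    scale = 65535.0 if arr.dtype == np.uint16 else 255.0
    return arr.astype(np.float32) / scale
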