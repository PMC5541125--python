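"""Synthetic fracture phantom: meshes, fiducial placement, fluoroscopic renders.

Generates everything the physical study would acquire, with ground truth:

* a procedural distal-femur-like solid (generalised cylinder: circular
  shaft flaring into a two-lobed condylar mass) fractured into three
  fragments — FEM (shaft), F1 and F2 (condylar pieces) — by one
  transverse cut plus one sagittal (T-type) or helicoidally tilted
  (Y-type analogue) cut, with every cut face labelled as fracture
  surface;
* an orthopaedic pin + registration tool rigidly attached to each
  fragment (randomised insertion pose per seed);
* two-view fluoroscopic renders (silhouette shading, not X-ray
  transport: the downstream operators consume edges and blobs) with
  controllable pixel noise, feature-localisation jitter, smooth contour
  perturbation, lateral-view occlusion and optional distortion;
* a calibration-grid image generator.

Vertices can be quantised to the CT voxel size (0.58 x 0.58 x 0.75 mm by
default) to emulate CT discretisation.  Everything is deterministic given
the spec and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import shapely
import trimesh
from PIL import Image, ImageDraw
from scipy import ndimage
from scipy.spatial.transform import Rotation

from .calibration import BeadGridModel
from .config import default_fiducial, noise_profile
from .contours import Contour2D
from .errors import MeshError, RenderError
from .fiducial import FiducialGeometry
from .geometry import CArmModel, RigidTransform

__all__ = [
    "PhantomSpec",
    "FragmentScene",
    "GroundTruthView",
    "generate_phantom",
    "render_view",
    "render_calibration_image",
    "orbit_camera_pose",
    "nominal_rt_in_fragment",
]

FRAGMENTS = ("FEM", "F1", "F2")  # pins P0, P1, P2 respectively

# bone shape profile knots: height (mm) -> base radius (mm), lobe amplitude
_PROFILE_Y = np.array([0.0, 4.0, 12.0, 30.0, 45.0, 60.0, 200.0])
_PROFILE_R = np.array([6.0, 13.0, 17.0, 18.0, 16.0, 14.0, 14.0])
_PROFILE_A = np.array([0.30, 0.45, 0.55, 0.55, 0.25, 0.0, 0.0])


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of the synthetic fractured-femur phantom."""

    fracture_type: str = "Y"  # "Y" or "T" (three-part articular analogue)
    length: float = 130.0  # mm, distal articular end (y=0) to proximal cut-off
    shaft_radius: float = 14.0  # mm
    condyle_radius: float = 18.0  # mm, base radius of the condylar mass
    cut_y: float = 50.0  # mm, transverse fracture plane
    cut_obliquity: tuple = (0.07, 0.14)  # dy/dx, dy/dz slopes of the "transverse" cut
    cut_wave_mm: float = 2.5  # amplitude of the jagged fracture-line undulation
    cut_wave_lobes: int = 3
    shaft_bow: float = 6.0  # mm, anterior bow sagitta (breaks axial symmetry)
    shaft_ellipticity: float = 0.12  # relative a-p flattening of the shaft
    sagittal_tilt_deg: float = 25.0  # Y-type: max helicoidal tilt of the distal cut
    ct_voxel: tuple = (0.58, 0.58, 0.75)  # mm
    quantise: bool = True
    noise: dict = field(default_factory=lambda: dict(noise_profile("clean")))
    standoff: float = 700.0  # mm, source-to-isocentre distance
    n_theta: int = 32
    n_arc: int = 18
    n_chord: int = 8
    seed: int = 0

    def __post_init__(self):
        if self.fracture_type not in ("Y", "T"):
            raise ValueError("fracture_type must be 'Y' or 'T'")


@dataclass
class GroundTruthView:
    """Per-view ground truth recorded pre-noise (features as imaged)."""

    fragment: str
    view_angle_deg: float
    camera_pose: RigidTransform  # world -> camera
    image_pose: RigidTransform  # RT frame -> camera (the pose a view estimator recovers)
    features_px: np.ndarray  # (4, 2): bead1..3, pin tip
    silhouette: Contour2D  # fragment outline, as imaged, pre-perturbation


@dataclass
class FragmentScene:
    """Three fragment meshes with fiducials and ground-truth poses."""

    spec: PhantomSpec
    meshes: dict  # name -> trimesh.Trimesh (model/CT frame)
    fracture_faces: dict  # name -> (k,) int face indices
    rt_in_frag: dict  # name -> RigidTransform (RT frame -> fragment model frame)
    frag_world: dict  # name -> RigidTransform (fragment model frame -> world)
    fiducial: FiducialGeometry
    log: list = field(default_factory=list)

    def rt_world(self, name: str) -> RigidTransform:
        return self.frag_world[name] @ self.rt_in_frag[name]

    def true_fragment_pose_in_rt(self, name: str) -> RigidTransform:
        """Ground-truth fragment pose in its RT/pin frame (the sTRE reference)."""
        return self.rt_in_frag[name].inverse()

    def view_center(self, name: str) -> np.ndarray:
        """World isocentre for imaging this fragment + its fiducial."""
        mesh_c = self.frag_world[name].apply(self.meshes[name].vertices.mean(axis=0))
        feat_c = self.rt_world(name).apply(self.fiducial.points).mean(axis=0)
        return 0.5 * (mesh_c + feat_c)


# ---------------------------------------------------------------------------
# procedural bone geometry
# ---------------------------------------------------------------------------

def _radius(theta: np.ndarray, y: float, spec: PhantomSpec) -> np.ndarray:
    scale = spec.condyle_radius / 18.0
    R = np.interp(y, _PROFILE_Y, _PROFILE_R) * scale
    if y >= 60.0:
        R = spec.shaft_radius
    A = np.interp(y, _PROFILE_Y, _PROFILE_A)
    return R * (1.0 + A * np.cos(theta) ** 2)


def _section_xy(theta: np.ndarray, y: float, spec: PhantomSpec) -> np.ndarray:
    r = _radius(theta, y, spec)
    # mild antero-posterior flattening of the shaft (ramps in above the
    # condylar mass) and an anterior bow: a real shaft is neither circular
    # nor straight, which is what makes its axial spin observable in a
    # silhouette
    e = spec.shaft_ellipticity * np.clip((y - 45.0) / 25.0, 0.0, 1.0)
    r = r * (1.0 - e * np.sin(theta) ** 2)
    z_off = -spec.shaft_bow * np.sin(np.pi * np.clip(y, 0.0, spec.length) / spec.length)
    return np.stack([r * np.cos(theta), r * np.sin(theta) + z_off], axis=1)


def _cut_angle(y: float, spec: PhantomSpec) -> float:
    """In-plane angle of the distal cut line at height y (radians)."""
    if spec.fracture_type == "T":
        return 0.0
    t = np.clip((y - spec.cut_y / 2.0) / (spec.cut_y / 2.0), -1.0, 1.0)
    return np.radians(spec.sagittal_tilt_deg) * t


def _crossings(y: float, spec: PhantomSpec) -> tuple[float, float]:
    """Angles where the cut line { n.(x,z) = 0 } crosses the section curve.

    The cut contains the bone axis, so the crossings are where the radial
    direction is perpendicular to the cut normal: independent of r.
    """
    phi = _cut_angle(y, spec)
    # normal n = (cos phi, sin phi); crossing when cos(theta - (phi + pi/2)) = 0
    return phi + np.pi / 2.0, phi + 3.0 * np.pi / 2.0


def _cut_plane_y(pts_xz: np.ndarray, spec: PhantomSpec) -> np.ndarray:
    """Height of the oblique 'transverse' fracture plane over section points.

    A perfectly transverse supracondylar cut would leave the shaft's spin
    about its own axis weakly observable in a silhouette; the slight
    obliquity and the jagged undulation of the fracture line (like a real
    fracture) make the cut rim pose-revealing.
    """
    sx, sz = spec.cut_obliquity
    theta = np.arctan2(pts_xz[:, 1], pts_xz[:, 0])
    # two incommensurate harmonics: no residual rotational symmetry
    wave = spec.cut_wave_mm * (
        np.sin(spec.cut_wave_lobes * theta + 0.7)
        + 0.6 * np.sin((spec.cut_wave_lobes + 2) * theta + 1.9)
    )
    return spec.cut_y + sx * pts_xz[:, 0] + sz * pts_xz[:, 1] + wave


def _tube_mesh(
    sections: list[np.ndarray], ys
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Closed tube over per-height section polygons (equal vertex counts).

    ``ys`` entries may be scalars or per-vertex arrays (oblique end rings).
    Returns (vertices, faces, bottom_cap_faces, top_cap_faces); side faces
    are everything else.
    """
    nv = len(sections[0])
    verts = []
    for pts, y in zip(sections, ys):
        yy = np.broadcast_to(np.asarray(y, float), (nv,))
        verts.append(np.column_stack([pts[:, 0], yy, pts[:, 1]]))
    verts = np.concatenate(verts)
    faces = []
    ns = len(sections)
    for i in range(ns - 1):
        for j in range(nv):
            a = i * nv + j
            b = i * nv + (j + 1) % nv
            c = (i + 1) * nv + (j + 1) % nv
            d = (i + 1) * nv + j
            faces.append([a, b, c])
            faces.append([a, c, d])
    n_side = len(faces)
    # caps: fan to a centre vertex (planar also for oblique end rings)
    c_bot = len(verts)
    verts = np.vstack(
        [verts, [[sections[0][:, 0].mean(), float(np.mean(ys[0])), sections[0][:, 1].mean()]]]
    )
    bot = []
    for j in range(nv):
        bot.append([c_bot, (j + 1) % nv, j])
    c_top = len(verts)
    verts = np.vstack(
        [verts, [[sections[-1][:, 0].mean(), float(np.mean(ys[-1])), sections[-1][:, 1].mean()]]]
    )
    top = []
    base = (ns - 1) * nv
    for j in range(nv):
        top.append([c_top, base + j, base + (j + 1) % nv])
    faces = np.asarray(faces + bot + top, int)
    bottom_idx = np.arange(n_side, n_side + nv)
    top_idx = np.arange(n_side + nv, n_side + 2 * nv)
    return verts, faces, bottom_idx, top_idx


def _finalise(verts, faces, spec: PhantomSpec) -> trimesh.Trimesh:
    mesh = trimesh.Trimesh(vertices=verts, faces=faces, process=False)
    if mesh.volume < 0:
        mesh.invert()
    return mesh


def _fem_mesh(spec: PhantomSpec):
    theta = np.linspace(0.0, 2 * np.pi, spec.n_theta, endpoint=False)
    ring = _section_xy(theta, spec.cut_y, spec)
    scalar_ys = np.concatenate(
        [
            np.linspace(spec.cut_y + 5.0, 60.0, 4, endpoint=False),
            np.linspace(60.0, spec.length, 9),
        ]
    )
    sections = [ring] + [_section_xy(theta, y, spec) for y in scalar_ys]
    ys = [_cut_plane_y(ring, spec)] + list(scalar_ys)
    verts, faces, bot, top = _tube_mesh(sections, ys)
    mesh = _finalise(verts, faces, spec)
    return mesh, bot  # bottom cap (at the oblique transverse cut) is the fracture surface


def _half_section(y: float, spec: PhantomSpec, side: int) -> np.ndarray:
    """Cross-section polygon of the distal fragment on one side of the cut."""
    th1, th2 = _crossings(y, spec)
    if side > 0:
        thetas = np.linspace(th2, th1 + 2 * np.pi, spec.n_arc)
    else:
        thetas = np.linspace(th1, th2, spec.n_arc)
    arc = _section_xy(thetas, y, spec)
    # chord from last arc point back to the first (interior points only)
    frac = np.arange(1, spec.n_chord + 1) / (spec.n_chord + 1)
    chord = arc[-1] + frac[:, None] * (arc[0] - arc[-1])
    return np.vstack([arc, chord])


def _distal_mesh(spec: PhantomSpec, side: int):
    scalar_ys = np.concatenate(
        [
            np.linspace(0.0, 12.0, 5, endpoint=False),
            np.linspace(12.0, spec.cut_y - 5.0, 9),
        ]
    )
    sections = [_half_section(y, spec, side) for y in scalar_ys]
    top_ring = _half_section(spec.cut_y, spec, side)
    sections.append(top_ring)
    ys = list(scalar_ys) + [_cut_plane_y(top_ring, spec)]
    verts, faces, bot, top = _tube_mesh(sections, ys)
    nv = spec.n_arc + spec.n_chord
    ns = len(sections)
    # side faces whose column index lies on the chord wall are fracture faces
    wall = []
    for i in range(ns - 1):
        for j in range(spec.n_arc - 1, nv):
            base = (i * nv + j) * 2
            wall.extend([base, base + 1])
    mesh = _finalise(verts, faces, spec)
    frac_faces = np.concatenate([np.asarray(wall, int), top])
    return mesh, frac_faces


def _quantise(mesh: trimesh.Trimesh, voxel) -> trimesh.Trimesh:
    v = np.asarray(mesh.vertices) / np.asarray(voxel)
    out = trimesh.Trimesh(
        vertices=np.round(v) * np.asarray(voxel), faces=mesh.faces, process=False
    )
    return out


def nominal_rt_in_fragment(name: str, spec: PhantomSpec) -> RigidTransform:
    """Nominal pin/RT attachment pose for a fragment (RT frame -> model frame).

    The pin enters the anterior surface (-z side), pointing between the two
    C-arm view directions and tilted distally so it is well foreshortened in
    neither view.  This nominal pose (without the per-seed randomisation) is
    also what the pipeline uses as its orientation prior for coarse
    alignment, mimicking the surgeon's knowledge of where the pin was
    placed.
    """
    a = np.array([-0.26, 0.0, -0.966])
    a = a + 0.7 * np.array([0.0, -1.0, 0.0])
    a /= np.linalg.norm(a)  # tip -> RT direction (outward, toward the source)
    entries = {
        "FEM": np.array([0.0, 95.0, -spec.shaft_radius]),
        "F1": np.array([14.0, 25.0, -14.0]),
        "F2": np.array([-14.0, 25.0, -14.0]),
    }
    entry = entries[name]
    depth = 10.0
    tip_target = entry - depth * a
    R = _rotation_to(a)
    fid = default_fiducial()
    t = tip_target - R @ fid.pin_tip
    return RigidTransform(R, t, validate=False)


def _rotation_to(direction: np.ndarray) -> np.ndarray:
    """A rotation taking +z to ``direction`` (minimal rotation)."""
    z = np.array([0.0, 0.0, 1.0])
    d = direction / np.linalg.norm(direction)
    v = np.cross(z, d)
    s = np.linalg.norm(v)
    c = float(z @ d)
    if s < 1e-12:
        return np.eye(3) if c > 0 else Rotation.from_euler("x", 180, degrees=True).as_matrix()
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx * ((1 - c) / s**2)


def generate_phantom(spec: PhantomSpec, fiducial: FiducialGeometry | None = None) -> FragmentScene:
    """Build the fractured phantom scene for a spec (deterministic per seed)."""
    fid = fiducial or default_fiducial()
    log = []
    for attempt in range(3):
        s = spec if attempt == 0 else replace(spec, cut_y=spec.cut_y + 2.0 * attempt)
        fem, fem_frac = _fem_mesh(s)
        f1, f1_frac = _distal_mesh(s, side=+1)
        f2, f2_frac = _distal_mesh(s, side=-1)
        meshes = {"FEM": fem, "F1": f1, "F2": f2}
        fracture = {"FEM": fem_frac, "F1": f1_frac, "F2": f2_frac}
        vols = {k: float(m.volume) for k, m in meshes.items()}
        if min(vols.values()) >= 1000.0:
            break
        log.append(f"degenerate cut (volumes {vols}), regenerating with shifted planes")
    else:
        raise MeshError("could not produce three fragments >= 1000 mm^3")

    for name, m in meshes.items():
        if not m.is_watertight:
            raise MeshError(f"generated fragment {name} is not watertight")
    if spec.quantise:
        meshes = {k: _quantise(m, spec.ct_voxel) for k, m in meshes.items()}

    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0xB0]))
    rt_in_frag = {}
    frag_world = {}
    for name in FRAGMENTS:
        nominal = nominal_rt_in_fragment(name, spec)
        # per-seed insertion variability: cone tilt, clocking, entry jitter
        tilt_axis = rng.normal(size=3)
        tilt_axis /= np.linalg.norm(tilt_axis)
        tilt = Rotation.from_rotvec(
            tilt_axis * np.radians(rng.uniform(0, 10.0))
        ).as_matrix()
        clock = Rotation.from_euler("z", rng.uniform(-10.0, 10.0), degrees=True).as_matrix()
        jitter = rng.uniform(-4.0, 4.0, size=3)
        rt_in_frag[name] = RigidTransform(
            tilt @ nominal.rotation @ clock, nominal.translation + jitter, validate=False
        )
        # intra-operative fragment displacement in the world frame
        ax = rng.normal(size=3)
        ax /= np.linalg.norm(ax)
        Rw = Rotation.from_rotvec(ax * np.radians(rng.uniform(0, 8.0))).as_matrix()
        frag_world[name] = RigidTransform(Rw, rng.uniform(-8.0, 8.0, size=3), validate=False)

    return FragmentScene(
        spec=spec,
        meshes=meshes,
        fracture_faces=fracture,
        rt_in_frag=rt_in_frag,
        frag_world=frag_world,
        fiducial=fid,
        log=log,
    )


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def orbit_camera_pose(center: np.ndarray, angle_deg: float, radius: float) -> RigidTransform:
    """World -> camera transform of the C-arm at an orbit angle.

    The orbit axis is the world y axis; the source sits at
    ``center - radius * d(angle)`` with ``d = (cos a, 0, sin a)``, looking
    through ``center``.  Two views at 90 deg and 60 deg therefore differ by
    an exact 30 deg rotation about the orbit axis.
    """
    a = np.radians(angle_deg)
    d = np.array([np.cos(a), 0.0, np.sin(a)])  # camera z (view direction)
    x = np.array([-np.sin(a), 0.0, np.cos(a)])  # orbit tangent
    y = np.cross(d, x)
    R = np.stack([x, y, d])  # rows: world -> camera
    source = center - radius * d
    return RigidTransform(R, -R @ source, validate=False)


def _project_px(carm: CArmModel, cam_pts: np.ndarray, distort: bool) -> np.ndarray:
    z = cam_pts[:, 2]
    uv = cam_pts[:, :2] * (carm.sid / z)[:, None] / carm.pixel_size + np.asarray(
        carm.principal_point
    )
    if distort and carm.distortion is not None:
        uv = carm.distortion.apply(uv)
    return uv


def _silhouette_polygon(mesh, carm, cam_from_model: RigidTransform, distort: bool):
    cam = cam_from_model.apply(np.asarray(mesh.vertices, float))
    if (cam[:, 2] <= 0).any():
        raise RenderError("mesh behind the X-ray source")
    uv = _project_px(carm, cam, distort)
    polys = shapely.make_valid(shapely.polygons(uv[np.asarray(mesh.faces)]))
    union = shapely.union_all(polys)
    if union.geom_type == "MultiPolygon":
        union = max(union.geoms, key=lambda g: g.area)
    return union


def _perturb_polygon(poly, sigma_px: float, rng, corr_samples: int = 25):
    """Smooth normal perturbation of a polygon ring (contour noise model)."""
    ring = poly.exterior
    n = max(64, int(ring.length / 2.0))
    t = np.linspace(0.0, ring.length, n, endpoint=False)
    pts = shapely.get_coordinates(shapely.line_interpolate_point(ring, t))
    tang = np.roll(pts, -1, axis=0) - np.roll(pts, 1, axis=0)
    tang /= np.linalg.norm(tang, axis=1)[:, None]
    nrm = np.stack([-tang[:, 1], tang[:, 0]], axis=1)
    raw = rng.standard_normal(n)
    kernel = np.exp(-0.5 * (np.arange(-3 * corr_samples, 3 * corr_samples + 1) / corr_samples) ** 2)
    smooth = np.convolve(np.tile(raw, 3), kernel / kernel.sum(), mode="same")[n : 2 * n]
    if smooth.std() > 0:
        smooth = smooth / smooth.std() * sigma_px
    out = shapely.Polygon(pts + smooth[:, None] * nrm)
    if not out.is_valid:
        out = shapely.make_valid(out)
        if out.geom_type == "GeometryCollection":
            out = max(
                (g for g in out.geoms if g.geom_type == "Polygon"),
                key=lambda g: g.area,
            )
        if out.geom_type == "MultiPolygon":
            out = max(out.geoms, key=lambda g: g.area)
    return out


_SS = 4  # rasterisation supersampling factor


def _rasterise(polygons, shape, ss=_SS) -> np.ndarray:
    """Anti-aliased coverage raster of shapely polygons (supersampled).

    Only the polygons' (padded) bounding window is rasterised at the
    supersampled resolution and pasted into the full-frame output.
    """
    h, w = shape
    out = np.zeros((h, w), dtype=np.float32)
    polys = [p for p in polygons if not p.is_empty]
    if not polys:
        return out
    bounds = np.array([p.bounds for p in polys])
    u0 = max(0, int(np.floor(bounds[:, 0].min())) - 2)
    v0 = max(0, int(np.floor(bounds[:, 1].min())) - 2)
    u1 = min(w, int(np.ceil(bounds[:, 2].max())) + 2)
    v1 = min(h, int(np.ceil(bounds[:, 3].max())) + 2)
    if u1 <= u0 or v1 <= v0:
        return out
    bw, bh = u1 - u0, v1 - v0
    img = Image.new("L", (bw * ss, bh * ss), 0)
    draw = ImageDraw.Draw(img)
    # integer array index = pixel centre, while PIL's pixel (i, j) is the
    # unit square [i, i+1): shift by half a pixel before supersampling.
    # PIL also strokes the outline while filling, dilating the shape by a
    # fraction of a subpixel; erode by the measured amount (0.3 subpixel,
    # from the disk edge-position check) to keep rendered edges unbiased.
    polys = [shapely.buffer(p, -0.3 / ss) for p in polys]
    polys = [p for p in polys if not p.is_empty]
    for poly in polys:
        geoms = poly.geoms if poly.geom_type == "MultiPolygon" else [poly]
        for g in geoms:
            xy = [
                ((x - u0 + 0.5) * ss, (y - v0 + 0.5) * ss)
                for x, y in np.asarray(g.exterior.coords)
            ]
            draw.polygon(xy, fill=255)
            for hole in g.interiors:
                xy = [
                    ((x - u0 + 0.5) * ss, (y - v0 + 0.5) * ss)
                    for x, y in np.asarray(hole.coords)
                ]
                draw.polygon(xy, fill=0)
    arr = np.asarray(img, dtype=np.float32) / 255.0
    out[v0:v1, u0:u1] = arr.reshape(bh, ss, bw, ss).mean(axis=(1, 3))
    return out


def _draw_disk(img: np.ndarray, center, radius_px: float, value: float):
    """Anti-aliased disk via signed-distance coverage, "over"-composited.

    Over-compositing (rather than max) keeps the anti-aliased edge ramp
    symmetric over any background level, so edge and centroid positions
    stay unbiased when a bead or pin overlaps the bone shadow.
    """
    h, w = img.shape
    u, v = center
    r = int(np.ceil(radius_px)) + 2
    u0, v0 = int(np.floor(u)), int(np.floor(v))
    us = slice(max(0, u0 - r), min(w, u0 + r + 1))
    vs = slice(max(0, v0 - r), min(h, v0 + r + 1))
    uu, vv = np.meshgrid(np.arange(us.start, us.stop), np.arange(vs.start, vs.stop))
    d = np.hypot(uu - u, vv - v)
    cov = np.clip(radius_px - d + 0.5, 0.0, 1.0)
    img[vs, us] = img[vs, us] * (1.0 - cov) + value * cov


def _pin_polygon(carm, cam_from_rt: RigidTransform, fid: FiducialGeometry, distort: bool):
    """Projected outline of the cylindrical pin (flat tip, local magnification)."""
    ts = np.linspace(0.0, 1.0, 8)
    axis_pts = fid.pin_tip + ts[:, None] * (fid.pin_top - fid.pin_tip)
    cam = cam_from_rt.apply(axis_pts)
    if (cam[:, 2] <= 0).any():
        raise RenderError("pin behind the X-ray source")
    uv = _project_px(carm, cam, distort)
    r_px = fid.pin_radius * (carm.sid / cam[:, 2]) / carm.pixel_size
    tang = np.gradient(uv, axis=0)
    tang /= np.linalg.norm(tang, axis=1)[:, None]
    nrm = np.stack([-tang[:, 1], tang[:, 0]], axis=1)
    left = uv + nrm * r_px[:, None]
    right = uv - nrm * r_px[:, None]
    return shapely.Polygon(np.vstack([left, right[::-1]]))


_FRAG_LEVEL = 0.45
_PIN_LEVEL = 0.92
_BEAD_LEVEL = 1.0
# overlap shadow: washes out the bone edge but stays below the metal
# threshold so the fiducial features remain detectable through it
_OCCLUSION_LEVEL = 0.50


def render_view(
    scene: FragmentScene,
    carm: CArmModel,
    view_angle_deg: float,
    noise: dict | None = None,
    seed: int = 0,
    fragment: str = "F1",
    is_lateral: bool | None = None,
) -> tuple[np.ndarray, GroundTruthView]:
    """Render one fluoroscopic view of fragment + pin + registration tool.

    Returns the image (float32, attenuation convention: metal bright on a
    dark background) and the pre-noise ground truth for the view.  The
    occlusion band of the cadaver-like profile is applied only to the
    lateral view (``is_lateral`` defaults to ``view_angle_deg != 90``).

    Raises
    ------
    RenderError
        If the fiducial or fragment falls outside the field of view.
    """
    nz = dict(noise_profile("clean"))
    if noise:
        nz.update(noise)
    if is_lateral is None:
        is_lateral = view_angle_deg != 90.0
    rng = np.random.default_rng(
        np.random.SeedSequence([seed, int(round(view_angle_deg * 10)), FRAGMENTS.index(fragment)])
    )
    distort = bool(nz.get("distortion")) and carm.distortion is not None

    center = scene.view_center(fragment)
    cam_pose = orbit_camera_pose(center, view_angle_deg, scene.spec.standoff)
    mesh = scene.meshes[fragment]
    frag_world = scene.frag_world[fragment]
    rt_world = scene.rt_world(fragment)
    cam_from_frag = cam_pose @ frag_world
    cam_from_rt = cam_pose @ rt_world

    fid = scene.fiducial
    feat_cam = cam_from_rt.apply(fid.points)
    if (feat_cam[:, 2] <= 0).any():
        raise RenderError("fiducial behind the X-ray source")
    features_px = _project_px(carm, feat_cam, distort)

    sil_poly = _silhouette_polygon(mesh, carm, cam_from_frag, distort)
    pin_poly = _pin_polygon(carm, cam_from_rt, fid, distort)

    # field-of-view check against the detector circle
    pp = np.asarray(carm.principal_point)
    fov_r = min(pp) - 15.0
    check = np.vstack([features_px, shapely.get_coordinates(sil_poly.exterior)])
    if (np.linalg.norm(check - pp, axis=1) > fov_r).any():
        raise RenderError(
            f"scene exceeds the field of view for fragment {fragment} at {view_angle_deg} deg"
        )

    # ground truth is recorded pre-noise
    ring = sil_poly.exterior
    t = np.linspace(0.0, ring.length, 400, endpoint=False)
    gt_sil = Contour2D(
        shapely.get_coordinates(shapely.line_interpolate_point(ring, t)),
        closed=True,
        smoothing=0.05,
    )
    gt = GroundTruthView(
        fragment=fragment,
        view_angle_deg=view_angle_deg,
        camera_pose=cam_pose,
        image_pose=cam_from_rt,
        features_px=features_px.copy(),
        silhouette=gt_sil,
    )

    # --- compose the image ------------------------------------------
    if nz["contour_sigma_px"] > 0:
        sil_draw = _perturb_polygon(sil_poly, nz["contour_sigma_px"], rng)
    else:
        sil_draw = sil_poly
    jit = nz["feature_jitter_px"]
    pin_draw = pin_poly
    if jit > 0:
        dx, dy = rng.normal(0.0, jit, size=2)
        pin_draw = shapely.transform(pin_poly, lambda p: p + [dx, dy])

    frag_mask = _rasterise([sil_draw], carm.image_shape)
    pin_mask = _rasterise([pin_draw], carm.image_shape)
    # metal "over" bone: keeps anti-aliased edge ramps symmetric over any
    # background so feature localisation stays unbiased
    img = _FRAG_LEVEL * frag_mask
    img = img * (1.0 - pin_mask) + _PIN_LEVEL * pin_mask
    metal = _PIN_LEVEL * pin_mask

    bead_r_px = 2.5 * (carm.sid / feat_cam[:3, 2]) / carm.pixel_size  # 5-mm beads
    for k in range(3):
        c = features_px[k]
        if jit > 0:
            c = c + rng.normal(0.0, jit, size=2)
        _draw_disk(img, c, bead_r_px[k], _BEAD_LEVEL)
        _draw_disk(metal, c, bead_r_px[k], _BEAD_LEVEL)

    if nz["blur_sigma_px"] > 0:
        img = ndimage.gaussian_filter(img, nz["blur_sigma_px"])
        metal = ndimage.gaussian_filter(metal, nz["blur_sigma_px"])

    occl = nz.get("occlusion_fraction_lat", 0.0)
    if occl > 0 and is_lateral:
        n = 256
        tt = np.linspace(0.0, ring.length, n, endpoint=False)
        pts = shapely.get_coordinates(shapely.line_interpolate_point(ring, tt))
        start = rng.integers(0, n)
        span = int(round(occl * n))
        arc = pts[(start + np.arange(span)) % n]
        band = shapely.buffer(shapely.LineString(arc), 25.0)
        m = _rasterise([band], carm.image_shape, ss=1)
        m = ndimage.gaussian_filter(m, 10.0)
        # the overlapping structure washes out the bone edge but the metal
        # features stay denser than any soft-tissue/bone overlap
        img = np.maximum(img * (1.0 - m) + _OCCLUSION_LEVEL * m, metal)

    if nz["pixel_noise"] > 0:
        img = img + rng.normal(0.0, nz["pixel_noise"], size=img.shape)

    return img.astype(np.float32), gt


def render_calibration_image(
    carm: CArmModel,
    grid: BeadGridModel | None = None,
    seed: int = 0,
    pixel_noise: float = 0.0,
    blur_sigma_px: float = 1.0,
) -> np.ndarray:
    """Render the grid phantom laid on the detector (unit magnification).

    Beads are drawn at the exact lattice positions (distorted iff the
    C-arm model carries a distortion); deterministic per seed.
    """
    grid = grid or BeadGridModel()
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xCA]))
    pos, _ = grid.ideal_lattice_px(carm)
    if carm.distortion is not None:
        pos = carm.distortion.apply(pos)
    img = np.zeros(carm.image_shape, dtype=np.float64)
    r_px = 0.5 * grid.bead_diameter / carm.pixel_size
    for c in pos:
        _draw_disk(img, c, r_px, 1.0)
    if blur_sigma_px > 0:
        img = ndimage.gaussian_filter(img, blur_sigma_px)
    if pixel_noise > 0:
        img = img + rng.normal(0.0, pixel_noise, size=img.shape)
    return img.astype(np.float32)
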