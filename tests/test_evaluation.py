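"""sTRE, fracture-surface sampling, the manipulator target-pose chain, RMSE."""

import numpy as np
import pytest
import trimesh
from scipy.spatial.transform import Rotation

from fluororeg.errors import FluororegError, MeshError
from fluororeg.evaluation import (
    DesiredPose,
    compute_stre,
    reduction_rmse,
    rfm_target_pose,
    sample_fracture_surface,
)
from fluororeg.geometry import RigidTransform, compose


@pytest.fixture()
def triangle_mesh():
    """A single unit right triangle, labelled as fracture surface."""
    m = trimesh.Trimesh(
        vertices=[[0, 0, 0], [1, 0, 0], [0, 1, 0]], faces=[[0, 1, 2]], process=False
    )
    return m, np.array([0])


class TestSampleFractureSurface:
    def test_deterministic_per_seed(self, scene):
        mesh = scene.meshes["F1"]
        faces = scene.fracture_faces["F1"]
        a = sample_fracture_surface(mesh, faces, 100, seed=0)
        b = sample_fracture_surface(mesh, faces, 100, seed=0)
        np.testing.assert_array_equal(a.points, b.points)

    def test_area_uniform_on_single_triangle(self, triangle_mesh):
        mesh, faces = triangle_mesh
        s = sample_fracture_surface(mesh, faces, 1000, seed=0)
        # all inside the triangle
        p = s.points
        assert (p[:, 0] >= 0).all() and (p[:, 1] >= 0).all()
        assert (p[:, 0] + p[:, 1] <= 1 + 1e-12).all()
        # centroid near the triangle centroid (1/3, 1/3)
        np.testing.assert_allclose(p.mean(axis=0)[:2], [1 / 3, 1 / 3], atol=1 / 3 * 0.05)

    def test_zero_points_valid(self, triangle_mesh):
        mesh, faces = triangle_mesh
        s = sample_fracture_surface(mesh, faces, 0, seed=0)
        assert s.points.shape == (0, 3)

    def test_unlabelled_mesh_raises(self, triangle_mesh):
        mesh, _ = triangle_mesh
        with pytest.raises(MeshError):
            sample_fracture_surface(mesh, np.array([], int), 10)


class TestComputeStre:
    def test_identical_poses_zero(self, triangle_mesh):
        mesh, faces = triangle_mesh
        s = sample_fracture_surface(mesh, faces, 50, seed=1)
        T = RigidTransform.identity()
        rep = compute_stre(s, T, T)
        assert rep.mean == 0.0 and rep.sd == 0.0

    def test_unit_translation_gives_unit_distance(self, triangle_mesh):
        mesh, faces = triangle_mesh
        s = sample_fracture_surface(mesh, faces, 50, seed=1)
        shifted = RigidTransform(np.eye(3), [1.0, 0.0, 0.0])
        rep = compute_stre(s, RigidTransform.identity(), shifted)
        assert rep.mean == pytest.approx(1.0, abs=1e-12)
        assert rep.sd == pytest.approx(0.0, abs=1e-12)

    def test_rotation_matches_per_point_oracle(self, triangle_mesh):
        mesh, faces = triangle_mesh
        s = sample_fracture_surface(mesh, faces, 200, seed=2)
        c = s.points.mean(axis=0)
        R = Rotation.from_euler("z", 1.0, degrees=True).as_matrix()
        # rotation about an axis through the sample centroid
        rot = RigidTransform(R, c - R @ c)
        rep = compute_stre(s, RigidTransform.identity(), rot)
        oracle = np.linalg.norm((s.points - c) @ R.T - (s.points - c), axis=1).mean()
        assert rep.mean == pytest.approx(oracle, rel=1e-12)

    def test_empty_samples_raise(self, triangle_mesh):
        mesh, faces = triangle_mesh
        s = sample_fracture_surface(mesh, faces, 0, seed=0)
        with pytest.raises(FluororegError):
            compute_stre(s, RigidTransform.identity(), RigidTransform.identity())

    def test_invariant_under_common_rigid_motion(self, triangle_mesh, rng):
        mesh, faces = triangle_mesh
        s = sample_fracture_surface(mesh, faces, 100, seed=3)
        a, b = RigidTransform.random(rng), RigidTransform.random(rng)
        G = RigidTransform.random(rng)
        r1 = compute_stre(s, a, b)
        r2 = compute_stre(s, compose(G, a), compose(G, b))
        assert r1.mean == pytest.approx(r2.mean, abs=1e-9)

    def test_triangle_inequality_upper_bound(self, triangle_mesh, rng):
        mesh, faces = triangle_mesh
        s = sample_fracture_surface(mesh, faces, 100, seed=4)
        c = s.points.mean(axis=0)
        theta = np.radians(7.0)
        t = np.array([0.8, -0.5, 0.3])
        R = Rotation.from_rotvec([0, 0, theta]).as_matrix()
        pose = RigidTransform(R, c - R @ c + t)
        rep = compute_stre(s, RigidTransform.identity(), pose)
        r_max = np.linalg.norm(s.points - c, axis=1).max()
        bound = np.linalg.norm(t) + 2 * np.sin(theta / 2) * r_max
        assert rep.mean <= bound + 1e-9


class TestRfmTargetPose:
    def test_identity_chain_returns_input(self, rng):
        d = DesiredPose(RigidTransform.random(rng), frame="F1")
        out = rfm_target_pose(RigidTransform.identity(), RigidTransform.identity(), d)
        assert out.pose.allclose(d.pose)

    def test_matches_triple_product_oracle(self):
        rng = np.random.default_rng(6)
        a, b, c = (RigidTransform.random(rng) for _ in range(3))
        out = rfm_target_pose(a, b, DesiredPose(c))
        np.testing.assert_allclose(
            out.pose.matrix, a.matrix @ b.matrix @ c.matrix, atol=1e-9
        )

    def test_order_sensitivity_guard(self):
        """Swapping the composition order must change the result (the chain
        is directional: manipulator <- image space <- planned pose)."""
        rng = np.random.default_rng(7)
        a, b, c = (RigidTransform.random(rng) for _ in range(3))
        out = rfm_target_pose(a, b, DesiredPose(c))
        swapped = b.matrix @ a.matrix @ c.matrix
        assert not np.allclose(out.pose.matrix, swapped, atol=1e-6)

    def test_associativity_consistency(self):
        rng = np.random.default_rng(8)
        a, b, c = (RigidTransform.random(rng) for _ in range(3))
        lhs = (a @ b) @ c
        rhs = a @ (b @ c)
        assert lhs.allclose(rhs, atol=1e-9)


class TestReductionRmse:
    probe = np.array([[10.0, 0, 0], [0, 10.0, 0], [0, 0, 10.0]])

    def test_equal_poses_zero(self, rng):
        poses = [RigidTransform.random(rng) for _ in range(4)]
        dt, dr = reduction_rmse(poses, poses, self.probe)
        assert dt == pytest.approx(0.0, abs=1e-9)
        # arccos near +1 amplifies float noise; 1e-4 deg is numerically zero
        assert dr == pytest.approx(0.0, abs=1e-4)

    def test_uniform_2mm_offset(self, rng):
        desired = [RigidTransform.random(rng) for _ in range(3)]
        achieved = [
            RigidTransform(p.rotation, p.translation + [2.0, 0, 0]) for p in desired
        ]
        dt, dr = reduction_rmse(achieved, desired, self.probe)
        assert dt == pytest.approx(2.0, abs=1e-9)

    def test_mixed_offsets_hand_rmse(self):
        desired = [RigidTransform.identity() for _ in range(4)]
        achieved = [
            RigidTransform(np.eye(3), [d, 0, 0]) for d in (1.0, 2.0, 2.0, 3.0)
        ]
        dt, _ = reduction_rmse(achieved, desired, self.probe)
        assert dt == pytest.approx(np.sqrt((1 + 4 + 4 + 9) / 4), abs=1e-9)

    def test_length_mismatch_raises(self):
        with pytest.raises(FluororegError):
            reduction_rmse([RigidTransform.identity()], [], self.probe)
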