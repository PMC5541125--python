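"""Fiducial feature detection and perspective-4-point view pose estimation."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from fluororeg.errors import DetectionError, LabelingError
from fluororeg.fiducial import (
    FeatureDetections,
    FiducialGeometry,
    detect_features,
    estimate_image_pose,
)
from fluororeg.geometry import RigidTransform, project_points
from fluororeg.phantom import render_view


def _random_view_pose(rng, standoff=600.0):
    T = RigidTransform.random(rng, max_translation=30, max_angle_deg=40)
    return RigidTransform(T.rotation, T.translation + [0, 0, standoff], validate=False)


class TestFiducialGeometry:
    def test_default_geometry_valid(self, fiducial):
        pts = fiducial.points
        assert pts.shape == (4, 3)

    def test_coplanar_points_rejected(self):
        with pytest.raises(LabelingError):
            FiducialGeometry(
                bead_centers=[[0, 0, 0], [30, 0, 0], [0, 30, 0]],
                pin_tip=[10, 10, 0.1],
            )

    def test_ambiguous_distances_rejected(self):
        # two equal bead-to-bead distances
        with pytest.raises(LabelingError):
            FiducialGeometry(
                bead_centers=[[0, 0, 30], [30, 0, 30], [15, 26, 60]],
                pin_tip=[0, 0, -60],
            )


class TestDetectFeatures:
    def test_noiseless_detection_accuracy(self, scene, carm, fiducial):
        img, gt = render_view(scene, carm, 90.0, fragment="F1", seed=0)
        det = detect_features(img, carm, fiducial)
        err = np.linalg.norm(det.points - gt.features_px, axis=1)
        assert err[:3].max() < 0.1  # beads
        assert err[3] < 0.8  # pin tip: flat-end localisation is coarser

    def test_empty_image_raises(self, carm, fiducial):
        with pytest.raises(DetectionError):
            detect_features(np.zeros(carm.image_shape), carm, fiducial)

    def test_noisy_blurred_detection(self, scene, carm, fiducial):
        nz = {"pixel_noise": 0.02, "blur_sigma_px": 1.0}
        img, gt = render_view(scene, carm, 90.0, noise=nz, seed=5, fragment="F1")
        det = detect_features(img, carm, fiducial)
        err = np.linalg.norm(det.points - gt.features_px, axis=1)
        assert err[:3].mean() < 0.5


class TestEstimateImagePose:
    def test_exact_round_trip_identity_standoff(self, carm, fiducial):
        pose = RigidTransform(np.eye(3), [0, 0, 600.0])
        uv = project_points(carm, pose, fiducial.points, apply_dist=False)
        est = estimate_image_pose(FeatureDetections(uv), fiducial, carm)
        dt, dr = pose.distance_to(est.pose)
        assert dt < 0.01 and dr < 0.01

    def test_hundred_random_poses_recovered(self, carm, fiducial):
        rng = np.random.default_rng(11)
        for _ in range(100):
            pose = _random_view_pose(rng)
            uv = project_points(carm, pose, fiducial.points, apply_dist=False)
            est = estimate_image_pose(FeatureDetections(uv), fiducial, carm)
            dt, dr = pose.distance_to(est.pose)
            assert dt < 0.05 and dr < 0.05
            assert est.rms_reprojection < 1e-3

    def test_ap_lat_relative_rotation_is_30_deg(self, scene, carm, fiducial):
        """The two orbit views differ by exactly the 90-60 = 30 deg orbit arc."""
        poses = {}
        for ang in (90.0, 60.0):
            img, _ = render_view(scene, carm, ang, fragment="F1", seed=0)
            det = detect_features(img, carm, fiducial)
            poses[ang] = estimate_image_pose(det, fiducial, carm).pose
        rel = poses[90.0] @ poses[60.0].inverse()
        assert rel.rotation_angle_deg() == pytest.approx(30.0, abs=0.1)

    def test_rms_consistent_with_stored_residuals(self, carm, fiducial, rng):
        pose = _random_view_pose(rng)
        uv = project_points(carm, pose, fiducial.points, apply_dist=False)
        uv = uv + rng.normal(0, 0.5, uv.shape)
        est = estimate_image_pose(FeatureDetections(uv), fiducial, carm)
        reproj = project_points(carm, est.pose, fiducial.points, apply_dist=False)
        res = np.linalg.norm(reproj - uv, axis=1)
        np.testing.assert_allclose(est.per_point_residuals, res, atol=1e-9)
        assert est.rms_reprojection == pytest.approx(np.sqrt((res**2).mean()), abs=1e-9)

    def test_error_monotone_in_detection_noise(self, carm, fiducial):
        """Median pose error must not decrease as feature noise grows."""
        medians = []
        for sigma in (0.0, 0.25, 0.5, 1.0):
            errs = []
            for s in range(50):
                rng = np.random.default_rng(1000 + s)
                pose = _random_view_pose(rng)
                uv = project_points(carm, pose, fiducial.points, apply_dist=False)
                uv = uv + rng.normal(0, sigma, uv.shape)
                det = FeatureDetections(uv, covariance_px2=sigma**2)
                est = estimate_image_pose(det, fiducial, carm)
                errs.append(pose.distance_to(est.pose)[0])
            medians.append(np.median(errs))
        assert all(m1 <= m2 + 1e-9 for m1, m2 in zip(medians, medians[1:]))

    def test_refined_beats_coarse_grid_oracle(self, carm, fiducial):
        """The refined pose's reprojection RMS is <= every pose on a coarse
        6-DOF grid around the truth (oracle-equivalence check)."""
        rng = np.random.default_rng(4)
        pose = _random_view_pose(rng)
        uv = project_points(carm, pose, fiducial.points, apply_dist=False)
        uv_n = uv + rng.normal(0, 0.3, uv.shape)
        est = estimate_image_pose(FeatureDetections(uv_n), fiducial, carm, tip_weight=1.0)

        def rms(p):
            re = project_points(carm, p, fiducial.points, apply_dist=False) - uv_n
            return np.sqrt((np.linalg.norm(re, axis=1) ** 2).mean())

        deltas = np.array([-5.0, -2.5, 0.0, 2.5, 5.0])
        best = np.inf
        for dx in deltas:
            for dy in deltas:
                for dz in deltas:
                    cand_t = RigidTransform(
                        pose.rotation, pose.translation + [dx, dy, dz], validate=False
                    )
                    best = min(best, rms(cand_t))
        for ax in np.eye(3):
            for da in deltas:
                R = Rotation.from_rotvec(ax * np.radians(da)).as_matrix()
                cand = RigidTransform(R @ pose.rotation, pose.translation, validate=False)
                best = min(best, rms(cand))
        assert rms(est.pose) <= best + 1e-9
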