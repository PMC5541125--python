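"""Contour registration: cost, Gauss-Newton fit, coarse search, pin transform."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from fluororeg.geometry import RigidTransform, compose, invert
from fluororeg.phantom import orbit_camera_pose, render_view
from fluororeg.registration import (
    ContourRegistration,
    coarse_align,
    pin_to_fragment,
)


@pytest.fixture(scope="module")
def gt_setup(scene):
    """Ground-truth contours and image poses for fragment F1 (clean)."""
    from fluororeg.config import default_carm

    carm = default_carm()
    contours, poses = [], []
    for ang in (90.0, 60.0):
        _, gt = render_view(scene, carm, ang, fragment="F1", seed=0)
        contours.append(gt.silhouette)
        poses.append(gt.image_pose)
    truth = scene.true_fragment_pose_in_rt("F1")
    return scene.meshes["F1"], contours, poses, truth, carm




def _perturbed_contour(contour, sigma, rng):
    """Smooth correlated normal perturbation of a closed contour (px)."""
    pts = contour.points
    n = len(pts)
    tang = np.roll(pts, -1, axis=0) - np.roll(pts, 1, axis=0)
    tang /= np.linalg.norm(tang, axis=1)[:, None]
    nrm = np.stack([-tang[:, 1], tang[:, 0]], axis=1)
    raw = rng.standard_normal(n)
    k = np.exp(-0.5 * (np.arange(-30, 31) / 10.0) ** 2)
    sm = np.convolve(np.tile(raw, 3), k / k.sum(), mode="same")[n : 2 * n]
    if sm.std() > 0:
        sm = sm / sm.std() * sigma
    from fluororeg.contours import Contour2D

    return Contour2D(pts + sm[:, None] * nrm, closed=True, smoothing=0.25)


def _perturb(pose, rng, t_mm, r_deg):
    ax = rng.normal(size=3)
    ax /= np.linalg.norm(ax)
    R = Rotation.from_rotvec(ax * np.radians(r_deg)).as_matrix()
    dt = rng.normal(size=3)
    dt = dt / np.linalg.norm(dt) * t_mm
    return RigidTransform(R @ pose.rotation, pose.translation + dt, validate=False)


class TestRegisterFragment:
    def test_fixed_point_from_truth(self, gt_setup):
        mesh, contours, poses, truth, carm = gt_setup
        res = ContourRegistration(mesh, contours, poses, carm).fit(truth)
        dt, dr = truth.distance_to(res.fragment_pose)
        assert res.converged
        assert res.final_cost < 0.1
        assert dt < 0.05 and dr < 0.05

    def test_recovery_from_10mm_10deg_perturbation(self, gt_setup):
        mesh, contours, poses, truth, carm = gt_setup
        rng = np.random.default_rng(2)
        init = _perturb(truth, rng, 10.0, 10.0)
        res = ContourRegistration(mesh, contours, poses, carm).fit(init)
        dt, dr = truth.distance_to(res.fragment_pose)
        assert res.converged
        assert dt < 0.2 and dr < 0.3

    def test_single_view_depth_ambiguity(self, gt_setup):
        """With realistic contour noise, depth along the view axis is several
        times less certain from one view than from two (the perspective
        scale cue alone is noise-amplified; the second view triangulates)."""
        mesh, contours, poses, truth, carm = gt_setup
        depth_dir = poses[0].inverse().rotation @ np.array([0.0, 0.0, 1.0])
        init = RigidTransform(
            truth.rotation, truth.translation + 8.0 * depth_dir, validate=False
        )
        e1s, e2s = [], []
        for s in range(6):
            rng = np.random.default_rng(100 + s)
            noisy = [_perturbed_contour(c, 0.5, rng) for c in contours]
            res2 = ContourRegistration(mesh, noisy, poses, carm).fit(
                init, raise_on_max_iter=False
            )
            res1 = ContourRegistration(mesh, noisy[:1], poses[:1], carm).fit(
                init, raise_on_max_iter=False
            )
            e2s.append(abs((res2.fragment_pose.translation - truth.translation) @ depth_dir))
            e1s.append(abs((res1.fragment_pose.translation - truth.translation) @ depth_dir))
        assert np.median(e1s) >= 2.0 * np.median(e2s)

    def test_cost_trace_non_increasing(self, gt_setup):
        mesh, contours, poses, truth, carm = gt_setup
        rng = np.random.default_rng(5)
        init = _perturb(truth, rng, 8.0, 8.0)
        res = ContourRegistration(mesh, contours, poses, carm).fit(init)
        assert (np.diff(res.cost_trace) <= 1e-12).all()
        assert res.final_cost <= res.initial_cost

    def test_result_invariants(self, gt_setup):
        mesh, contours, poses, truth, carm = gt_setup
        res = ContourRegistration(mesh, contours, poses, carm).fit(truth)
        # pin_to_fragment with identity pin pose equals the fragment pose
        assert res.pin_to_fragment.allclose(res.fragment_pose)
        assert "Contour registration" in res.summary()


class TestPinToFragment:
    def test_same_pose_gives_identity(self, rng):
        T = RigidTransform.random(rng)
        assert pin_to_fragment(T, T).allclose(RigidTransform.identity(), atol=1e-9)

    def test_pure_translation(self):
        frag = RigidTransform(np.eye(3), [0.0, 0.0, 50.0])
        out = pin_to_fragment(frag, RigidTransform.identity())
        np.testing.assert_allclose(out.translation, [0, 0, 50])

    def test_matches_inverse_multiply_oracle(self):
        rng = np.random.default_rng(4)
        frag, pin = RigidTransform.random(rng), RigidTransform.random(rng)
        oracle = np.linalg.inv(pin.matrix) @ frag.matrix
        np.testing.assert_allclose(pin_to_fragment(frag, pin).matrix, oracle, atol=1e-9)

    def test_world_frame_equivariance(self, gt_setup):
        """A common world re-expression leaves the pin-to-fragment pose unchanged."""
        _, _, poses, truth, _ = gt_setup
        rng = np.random.default_rng(8)
        G = RigidTransform.random(rng, max_translation=50)
        pin = RigidTransform.identity()
        before = pin_to_fragment(truth, pin)
        after = pin_to_fragment(compose(G, truth), compose(G, pin))
        assert before.allclose(after, atol=1e-6)


class TestCoarseAlign:
    def test_truth_inside_search_box_found(self, gt_setup):
        mesh, contours, poses, truth, carm = gt_setup
        rng = np.random.default_rng(9)
        prior = _perturb(truth, rng, 10.0, 10.0)  # truth inside the +/-15 box
        found = coarse_align(mesh, contours, poses, carm, {"init_pose": prior}, seed=0)
        dt, dr = truth.distance_to(found)
        assert dt < 8.0 and dr < 8.0

    def test_zero_ranges_return_center(self, gt_setup):
        mesh, contours, poses, truth, carm = gt_setup
        out = coarse_align(
            mesh, contours, poses, carm,
            {"init_pose": truth, "translation_mm": 0.0, "rotation_deg": 0.0},
            seed=0,
        )
        assert out.allclose(truth)

    def test_seed_robustness_of_cost(self, gt_setup):
        mesh, contours, poses, truth, carm = gt_setup
        model = ContourRegistration(mesh, contours, poses, carm)
        costs = [
            model.cost(coarse_align(mesh, contours, poses, carm, seed=s))
            for s in (0, 1)
        ]
        assert abs(costs[0] - costs[1]) <= 0.2 * max(costs)

    def test_deterministic_given_seed(self, gt_setup):
        mesh, contours, poses, truth, carm = gt_setup
        a = coarse_align(mesh, contours, poses, carm, seed=3)
        b = coarse_align(mesh, contours, poses, carm, seed=3)
        assert a.allclose(b)
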