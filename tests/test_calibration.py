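"""Grid-phantom calibration: bead segmentation, matching, correction, pixel size."""

import numpy as np
import pytest

from fluororeg.calibration import (
    BeadGridModel,
    GridCalibration,
    GridCorrespondences,
    estimate_pixel_size,
    fit_distortion,
    match_grid,
    segment_beads,
)
from fluororeg.errors import CalibrationError, MatchingError
from fluororeg.geometry import RadialDistortion
from fluororeg.phantom import render_calibration_image


@pytest.fixture(scope="module")
def grid():
    return BeadGridModel(spacing=22.0, bead_diameter=10.0, n_rows=7, n_cols=7)


def _ideal_correspondences(grid, carm, noise=0.0, rng=None):
    pos, idx = grid.ideal_lattice_px(carm)
    det = pos.copy()
    if noise:
        det = det + rng.normal(0.0, noise, size=det.shape)
    return GridCorrespondences(detected=det, ideal=pos, lattice=idx)


class TestSegmentBeads:
    def test_noiseless_render_recovers_centers(self, carm, grid):
        img = render_calibration_image(carm, grid, seed=0)
        cents = segment_beads(img, grid.n_beads, min_radius_px=5)
        pos, _ = grid.ideal_lattice_px(carm)
        # match by nearest neighbour
        from scipy.spatial import cKDTree

        d, _ = cKDTree(pos).query(cents)
        assert len(cents) == 49
        assert d.max() < 0.05

    def test_blank_image_raises_coverage_error(self):
        with pytest.raises(CalibrationError, match="coverage"):
            segment_beads(np.zeros((200, 200)), expected_count=49)

    def test_noisy_grid_mean_error_below_threshold(self, carm, grid):
        img = render_calibration_image(carm, grid, seed=7, pixel_noise=0.02)
        cents = segment_beads(img, grid.n_beads, min_radius_px=5)
        pos, _ = grid.ideal_lattice_px(carm)
        from scipy.spatial import cKDTree

        d, _ = cKDTree(pos).query(cents)
        assert len(cents) == 49
        assert d.mean() < 0.3


class TestMatchGrid:
    def test_undistorted_grid_matches_identically(self, carm, grid):
        img = render_calibration_image(carm, grid, seed=0)
        cents = segment_beads(img, grid.n_beads, min_radius_px=5)
        corr = match_grid(cents, grid, carm)
        res = np.linalg.norm(corr.detected - corr.ideal, axis=1)
        assert len(corr) == 49
        assert res.max() < 0.1

    def test_rotated_grid_same_assignment(self, carm, grid):
        pos, idx = grid.ideal_lattice_px(carm)
        th = np.radians(5.0)
        R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        pp = np.asarray(carm.principal_point)
        rotated = (pos - pp) @ R.T + pp
        corr = match_grid(rotated, grid, carm)
        # the recovered lattice indices must equal the generating ones
        order = np.lexsort(corr.lattice.T)
        order0 = np.lexsort(idx.T)
        np.testing.assert_array_equal(corr.lattice[order], idx[order0])

    def test_duplicate_centroid_raises(self, carm, grid):
        pos, _ = grid.ideal_lattice_px(carm)
        dup = np.vstack([pos, pos[0] + [1.0, 1.0]])
        with pytest.raises(MatchingError):
            match_grid(dup, grid, carm)


class TestFitDistortion:
    def test_identity_correspondences_give_identity(self, carm, grid):
        corr = _ideal_correspondences(grid, carm)
        c = fit_distortion(corr, degree=3)
        assert c.fit_rms < 1e-6
        pts = np.random.default_rng(0).uniform(200, 800, size=(30, 2))
        np.testing.assert_allclose(c.apply(pts), pts, atol=1e-4)

    def test_heldout_residual_small_for_degree3(self, carm, grid):
        # intensifier-scale pincushion (~3 px at the periphery)
        dist = RadialDistortion(coefficients=(6e-8,), center=tuple(carm.principal_point))
        pos, idx = grid.ideal_lattice_px(carm)
        detected = dist.apply(pos)
        interior = (np.abs(idx) <= 2.0).all(axis=1)
        corr_fit = GridCorrespondences(detected[interior], pos[interior], idx[interior])
        c = fit_distortion(corr_fit, degree=3)
        held = ~interior
        res = np.linalg.norm(c.apply(detected[held]) - pos[held], axis=1)
        assert res.max() < 0.1

    def test_degree1_worse_than_degree3(self, carm, grid):
        dist = RadialDistortion(coefficients=(6e-8,), center=tuple(carm.principal_point))
        pos, idx = grid.ideal_lattice_px(carm)
        detected = dist.apply(pos)
        interior = (np.abs(idx) <= 2.0).all(axis=1)
        corr_fit = GridCorrespondences(detected[interior], pos[interior], idx[interior])
        held = ~interior
        res = {}
        for deg in (1, 3):
            c = fit_distortion(corr_fit, degree=deg)
            res[deg] = np.sqrt(
                (np.linalg.norm(c.apply(detected[held]) - pos[held], axis=1) ** 2).mean()
            )
        assert res[1] > res[3]

    def test_round_trip_dense_lattice(self, carm):
        grid = BeadGridModel(n_rows=9, n_cols=9)
        dist = RadialDistortion(
            coefficients=(6e-8, 2e-14), center=tuple(carm.principal_point)
        )
        pos, idx = grid.ideal_lattice_px(carm)
        corr = GridCorrespondences(dist.apply(pos), pos, idx)
        c = fit_distortion(corr, degree=3)
        # dense test lattice across the grid's span
        g = np.linspace(pos[:, 0].min(), pos[:, 0].max(), 25)
        dense = np.stack(np.meshgrid(g, g), axis=-1).reshape(-1, 2)
        res = np.linalg.norm(c.apply(dist.apply(dense)) - dense, axis=1)
        assert res.max() < 0.1


class TestPixelSize:
    def test_rendered_default_grid_recovers_printed_value(self, carm):
        # 22-mm pitch imaged at unit magnification on a 0.224 mm/px detector
        grid = BeadGridModel()
        result = GridCalibration(
            render_calibration_image(carm, grid, seed=0), grid, carm
        ).fit()
        assert result.pixel_size_estimate == pytest.approx(0.224, abs=1e-3)

    def test_pitch_doubling_halves_estimate(self, carm, grid):
        pos, idx = grid.ideal_lattice_px(carm)
        pp = np.asarray(carm.principal_point)
        corr1 = GridCorrespondences(pos, pos, idx)
        corr2 = GridCorrespondences((pos - pp) * 2 + pp, pos, idx)
        ps1 = estimate_pixel_size(corr1, grid)
        ps2 = estimate_pixel_size(corr2, grid)
        assert ps2 == pytest.approx(ps1 / 2, rel=1e-9)

    def test_noisy_estimate_within_half_percent(self, carm, grid):
        rng = np.random.default_rng(3)
        corr = _ideal_correspondences(grid, carm, noise=0.3, rng=rng)
        ps = estimate_pixel_size(corr, grid)
        assert ps == pytest.approx(0.224, rel=0.005)

    def test_estimator_unbiased_over_seeds(self, carm, grid):
        vals = []
        for s in range(50):
            rng = np.random.default_rng(s)
            corr = _ideal_correspondences(grid, carm, noise=0.3, rng=rng)
            vals.append(estimate_pixel_size(corr, grid))
        assert np.mean(vals) == pytest.approx(0.224, rel=0.002)

    def test_single_column_raises(self, carm, grid):
        pos, idx = grid.ideal_lattice_px(carm)
        col = idx[:, 0] == 0
        corr = GridCorrespondences(pos[col], pos[col], idx[col])
        with pytest.raises(CalibrationError):
            estimate_pixel_size(corr, grid)
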