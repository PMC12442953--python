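import numpy as np
import pytest

from intradental.fluor import ROI, ROISet
from intradental.ishreg import (ControlPoints, DemonsConfig, PolynomialWarp2,
                                WarpModel, apply_warp_stack, demons_refine,
                                efficiency_specificity, fit_polynomial_warp,
                                normalize_percentiles, transfer_rois)
from intradental.motion import mean_squares
from intradental.synthgen import generate_ish_pair


def generic_points(n=10, seed=0, lo=10.0, hi=150.0):
    rng = np.random.default_rng(seed)
    return np.column_stack([rng.uniform(lo, hi, n), rng.uniform(lo, hi, n)])


class TestNormalizePercentiles:
    def test_linear_ramp(self):
        ramp = np.linspace(0, 999, 1000).reshape(10, 100)
        out = normalize_percentiles(ramp)
        assert out.min() == 0.0 and out.max() == 1.0
        clipped = ((out == 0.0) | (out == 1.0)).sum()
        # ~0.1% at each tail
        assert clipped <= 6

    def test_constant_image_zeros_with_warning(self):
        with pytest.warns(UserWarning, match="degenerate"):
            out = normalize_percentiles(np.full((8, 8), 3.0))
        assert not out.any()

    def test_idempotent_on_normalized_ramp(self):
        ramp = np.linspace(0, 1, 100000).reshape(100, 1000)
        once = normalize_percentiles(ramp)
        twice = normalize_percentiles(once)
        interior = (once > 0) & (once < 1)
        assert np.abs(once[interior] - twice[interior]).max() < 1e-6


class TestPolynomialWarp:
    def test_identity_fit(self):
        pts = generic_points(6)
        warp = fit_polynomial_warp(ControlPoints(pts, pts))
        assert np.allclose(warp.coeffs_row, [0, 1, 0, 0, 0, 0], atol=1e-9)
        assert np.allclose(warp.coeffs_col, [0, 0, 1, 0, 0, 0], atol=1e-9)

    def test_exact_recovery_of_known_quadratic(self):
        true = PolynomialWarp2([2.0, 1.01, 0.02, 1e-4, -2e-4, 5e-5],
                               [-1.0, 0.01, 0.98, -1e-4, 1e-4, 2e-4])
        fixed = generic_points(10, seed=1)
        moving = true.map_points(fixed)
        fit = fit_polynomial_warp(ControlPoints(fixed, moving))
        assert np.abs(fit.coeffs_row - true.coeffs_row).max() < 1e-6
        assert np.abs(fit.coeffs_col - true.coeffs_col).max() < 1e-6

    def test_noisy_fit_residual_bounded(self):
        rng = np.random.default_rng(2)
        true = PolynomialWarp2([1.0, 1.0, 0.01, 0, 0, 0],
                               [0.5, 0.0, 1.0, 0, 0, 0])
        fixed = generic_points(10, seed=3)
        moving = true.map_points(fixed) + rng.normal(0, 0.5, (10, 2))
        fit = fit_polynomial_warp(ControlPoints(fixed, moving))
        resid = np.linalg.norm(fit.map_points(fixed) - moving, axis=1)
        assert np.sqrt((resid ** 2).mean()) <= 1.5

    def test_too_few_points_rejected(self):
        pts = generic_points(5)
        with pytest.raises(ValueError):
            ControlPoints(pts, pts)

    def test_degenerate_points_named_error(self):
        # all fixed points on a line (a degenerate conic)
        x = np.linspace(10, 100, 8)
        pts = np.column_stack([x, 2 * x])
        with pytest.raises(ValueError, match="rank deficient"):
            fit_polynomial_warp(ControlPoints(pts, pts))

    def test_duplicate_fixed_points_rejected(self):
        pts = generic_points(6)
        pts[1] = pts[0]
        with pytest.raises(ValueError, match="duplicated"):
            ControlPoints(pts, pts)


class TestDemons:
    def test_identical_images_near_zero_displacement(self):
        fixed, moving, truth = generate_ish_pair(warp_magnitude_px=0.0,
                                                 seed=4,
                                                 poly_warp=PolynomialWarp2())
        wm = demons_refine(fixed, moving[0], PolynomialWarp2())
        rms = np.sqrt((wm.displacement ** 2).sum(axis=-1).mean())
        assert rms < 0.05

    def test_landmark_error_after_refinement(self):
        fixed, moving, truth = generate_ish_pair(warp_magnitude_px=3.0,
                                                 seed=2)
        cps = ControlPoints(truth.true_control_points[:, 0],
                            truth.true_control_points[:, 1])
        poly = fit_polynomial_warp(cps)
        wm = demons_refine(fixed, moving[0], poly)
        probes = truth.true_control_points[:, 0]
        err = np.linalg.norm(wm.map_points(probes)
                             - truth.true_warp.map_points(probes), axis=1)
        assert np.sqrt((err ** 2).mean()) <= 1.0

    def test_metric_monotone_across_levels(self):
        fixed, moving, truth = generate_ish_pair(warp_magnitude_px=3.0,
                                                 seed=2)
        cps = ControlPoints(truth.true_control_points[:, 0],
                            truth.true_control_points[:, 1])
        wm = demons_refine(fixed, moving[0], fit_polynomial_warp(cps))
        seq = [wm.metadata["ms_init"]] + wm.metadata["metric_per_level"]
        assert all(b <= a + 1e-12 for a, b in zip(seq, seq[1:]))
        assert wm.metadata["ms_final"] <= wm.metadata["ms_init"]

    def test_non_overlapping_content_returns_init(self):
        rng = np.random.default_rng(0)
        fixed = np.zeros((64, 64))
        fixed[8:20, 8:20] = 1.0
        moving = rng.random((64, 64)) * 1e-3  # no shared structure
        with pytest.warns(UserWarning):
            wm = demons_refine(fixed, moving, PolynomialWarp2(),
                               DemonsConfig(n_levels=2,
                                            iterations_per_level=(2, 1)))
        # either rejected (zero displacement) or metric not worsened
        assert wm.metadata["ms_final"] <= wm.metadata["ms_init"] + 1e-12

    def test_config_validation(self):
        with pytest.raises(ValueError):
            DemonsConfig(n_levels=3, iterations_per_level=(5, 1, 1, 1))
        with pytest.raises(ValueError):
            DemonsConfig(iterations_per_level=(5, 1, 1, 0))


class TestWarpModel:
    def test_composition_order_is_polynomial_then_displacement(self):
        shape = (32, 32)
        poly = PolynomialWarp2([1.0, 1.0, 0.01, 0, 0, 0],
                               [-2.0, 0.0, 1.0, 0, 0, 0])
        disp = np.zeros(shape + (2,))
        disp[..., 0] = 0.5
        disp[..., 1] = -0.25
        wm = WarpModel(poly, disp, shape)
        pts = np.array([[4.0, 5.0], [10.0, 20.0]])
        expected = poly.map_points(pts) + np.array([0.5, -0.25])
        assert np.allclose(wm.map_points(pts), expected)

    def test_invert_points_round_trip(self):
        fixed, moving, truth = generate_ish_pair(warp_magnitude_px=3.0,
                                                 seed=6)
        wm = truth.true_warp
        pts = generic_points(8, seed=7, lo=30, hi=120)
        back = wm.invert_points(wm.map_points(pts))
        assert np.abs(back - pts).max() < 0.02


class TestApplyWarpStack:
    def test_identity_unchanged(self):
        rng = np.random.default_rng(1)
        stack = rng.random((3, 24, 24))
        out = apply_warp_stack(stack, WarpModel.identity((24, 24)))
        assert np.array_equal(out, stack)

    def test_alignment_reduces_mean_squares(self):
        fixed, moving, truth = generate_ish_pair(warp_magnitude_px=3.0,
                                                 seed=2)
        cps = ControlPoints(truth.true_control_points[:, 0],
                            truth.true_control_points[:, 1])
        wm = demons_refine(fixed, moving[0], fit_polynomial_warp(cps))
        aligned = apply_warp_stack(moving, wm)
        assert aligned.shape == moving.shape
        # compare interiors (borders are resampling fill)
        sl = (slice(None), slice(12, -12), slice(12, -12))
        before = mean_squares(fixed[sl[1:]], moving[0][sl[1:]])
        after = mean_squares(fixed[sl[1:]], aligned[0][sl[1:]])
        assert after <= 0.2 * before

    def test_channel_order_and_shape_preserved(self):
        fixed, moving, truth = generate_ish_pair(warp_magnitude_px=1.0,
                                                 seed=3, n_channels=4)
        aligned = apply_warp_stack(moving, truth.true_warp)
        assert aligned.shape == (4,) + fixed.shape


class TestTransferROIs:
    def _roiset(self, shape=(64, 64), center=(30, 30), radius=5):
        rr, cc = np.meshgrid(np.arange(shape[0]), np.arange(shape[1]),
                             indexing="ij")
        mask = (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius ** 2
        return ROISet([ROI("a", mask)], shape)

    def test_identity_warp_unchanged(self):
        rois = self._roiset()
        out = transfer_rois(rois, WarpModel.identity((64, 64)),
                            target="moving")
        assert np.array_equal(out.rois[0].mask, rois.rois[0].mask)

    def test_fixed_target_is_identity_overlay(self):
        rois = self._roiset()
        out = transfer_rois(rois, WarpModel.identity((64, 64)),
                            target="fixed")
        assert np.array_equal(out.rois[0].mask, rois.rois[0].mask)

    def test_pure_translation_moves_centroid(self):
        shape = (64, 64)
        poly = PolynomialWarp2([4.0, 1, 0, 0, 0, 0], [0.0, 0, 1, 0, 0, 0])
        wm = WarpModel(poly, np.zeros(shape + (2,)), shape)
        rois = self._roiset(shape)
        out = transfer_rois(rois, wm, target="moving")
        c_in = np.column_stack(np.nonzero(rois.rois[0].mask)).mean(axis=0)
        c_out = np.column_stack(np.nonzero(out.rois[0].mask)).mean(axis=0)
        assert np.abs(c_out - (c_in + [4.0, 0.0])).max() <= 0.5

    def test_area_preserved_under_smooth_warp(self):
        fixed, moving, truth = generate_ish_pair(warp_magnitude_px=3.0,
                                                 seed=8)
        rois = truth.true_rois
        out = transfer_rois(rois, truth.true_warp, target="moving")
        areas_in = {r.id: r.mask.sum() for r in rois}
        for r in out:
            # 15% for well-resolved ROIs; tiny discs carry a few px of
            # nearest-neighbour discretization jitter on top
            tol = max(0.15 * areas_in[r.id], 8)
            assert abs(int(r.mask.sum()) - int(areas_in[r.id])) <= tol
        total_in = sum(areas_in.values())
        total_out = sum(int(r.mask.sum()) for r in out)
        assert total_out == pytest.approx(total_in, rel=0.15)

    def test_out_of_grid_roi_dropped_with_warning(self):
        shape = (64, 64)
        poly = PolynomialWarp2([200.0, 1, 0, 0, 0, 0],
                               [200.0, 0, 1, 0, 0, 0])
        wm = WarpModel(poly, np.zeros(shape + (2,)), shape)
        rois = self._roiset(shape)
        with pytest.warns(UserWarning, match="dropped"):
            out = transfer_rois(rois, wm, target="moving")
        assert len(out) == 0


class TestEfficiencySpecificity:
    def test_all_positive(self):
        out = efficiency_specificity([True] * 10, [True] * 10)
        assert out == {"efficiency": 100.0, "specificity": 100.0}

    def test_worked_example(self):
        label = [True] * 50 + [False] * 50
        marker = [True] * 45 + [False] * 55
        out = efficiency_specificity(label, marker)
        assert out["efficiency"] == pytest.approx(50.0)
        assert out["specificity"] == pytest.approx(90.0)

    def test_zero_reporter_positive(self):
        out = efficiency_specificity([False] * 5, [True] * 5)
        assert out["efficiency"] == 0.0
        assert out["specificity"] is None

    def test_mismatched_shapes_rejected(self):
        with pytest.raises(ValueError):
            efficiency_specificity([True, False], [True])
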