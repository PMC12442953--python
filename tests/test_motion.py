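import numpy as np
import pytest

from intradental.motion import (AffineTransform2D, MovieStack,
                                OptimizerConfig, apply_transform,
                                estimate_translation, mean_squares,
                                refine_affine, register_stack)
from intradental.synthgen import (SynthMovieSpec, generate_movie,
                                  make_electrical_train)


def center_of(image):
    h, w = image.shape
    return np.array([(h - 1) / 2.0, (w - 1) / 2.0])


def shift_scene(scene, d, cval=100.0):
    """Move scene content by d (row, col): moving(x) = scene(x - d)."""
    t = AffineTransform2D.translation(-np.asarray(d), center_of(scene))
    return apply_transform(scene, t, cval=cval)


def integer_shift_oracle(fixed, moving, max_shift=10):
    """Exhaustive integer-shift search minimizing mean_squares over the
    overlap domain (independent of the gradient-descent path).

    Returns the shift s such that moving(x + s) best matches fixed(x),
    matching the transform convention of estimate_translation.
    """
    best, best_ms = (0, 0), np.inf
    h, w = fixed.shape
    for sr in range(-max_shift, max_shift + 1):
        for sc in range(-max_shift, max_shift + 1):
            f = fixed[max(0, -sr):h - max(0, sr),
                      max(0, -sc):w - max(0, sc)]
            m = moving[max(0, sr):h + min(0, sr),
                       max(0, sc):w + min(0, sc)]
            ms = float(np.mean((f - m) ** 2))
            if ms < best_ms:
                best_ms, best = ms, (sr, sc)
    return np.array(best, dtype=float)


class TestMeanSquares:
    def test_identical_images_zero(self, blob_scene):
        assert mean_squares(blob_scene, blob_scene) == 0.0

    def test_constant_difference(self, blob_scene):
        assert mean_squares(blob_scene, blob_scene + 3.0) == pytest.approx(9.0)

    def test_hand_computed_2x2(self):
        a = np.array([[0.0, 1.0], [2.0, 3.0]])
        b = np.array([[1.0, 1.0], [2.0, 3.0]])
        assert mean_squares(a, b) == pytest.approx(0.25)

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError):
            mean_squares(np.zeros((2, 2)), np.zeros((3, 3)))

    def test_nan_marks_out_of_domain(self):
        a = np.array([[0.0, 1.0], [2.0, 3.0]])
        b = a.copy()
        b[0, 0] = np.nan
        assert mean_squares(a, b) == 0.0


class TestApplyTransform:
    def test_identity_bit_exact(self, blob_scene):
        t = AffineTransform2D.identity(center_of(blob_scene))
        out = apply_transform(blob_scene, t)
        assert np.array_equal(out, blob_scene)

    def test_full_offgrid_shift_gives_zeros(self, blob_scene):
        h, w = blob_scene.shape
        t = AffineTransform2D.translation((h, w), center_of(blob_scene))
        assert not apply_transform(blob_scene, t).any()

    def test_round_trip_error_small(self, blob_scene):
        t = AffineTransform2D(np.array([[1.01, 0.02], [-0.015, 0.99]]),
                              np.array([1.3, -2.1]), center_of(blob_scene))
        once = apply_transform(blob_scene, t, cval=np.nan)
        back = apply_transform(np.nan_to_num(once, nan=100.0), t.inverse(),
                               cval=np.nan)
        valid = np.isfinite(back)
        mad = np.abs(back[valid] - blob_scene[valid]).mean()
        assert mad < 0.01 * np.ptp(blob_scene)

    def test_singular_linear_rejected(self):
        with pytest.raises(ValueError):
            AffineTransform2D(np.zeros((2, 2)), np.zeros(2))


class TestEstimateTranslation:
    def test_identical_images(self, blob_scene):
        t = estimate_translation(blob_scene, blob_scene)
        assert np.linalg.norm(t.offset) <= 0.01

    @pytest.mark.parametrize("shift", [(3.0, -2.0), (1.5, 0.0), (-5.0, 4.0)])
    def test_known_shift_recovered(self, blob_scene, shift):
        moving = shift_scene(blob_scene, shift)
        t = estimate_translation(blob_scene, moving)
        assert np.linalg.norm(t.offset - np.asarray(shift)) < 0.5

    def test_agrees_with_integer_oracle(self, blob_scene):
        moving = shift_scene(blob_scene, (4.0, -3.0))
        oracle = integer_shift_oracle(blob_scene, moving)
        t = estimate_translation(blob_scene, moving)
        assert np.linalg.norm(t.offset - oracle) < 0.5

    def test_constant_image_flagged(self):
        with pytest.warns(UserWarning, match="constant"):
            t = estimate_translation(np.full((32, 32), 5.0),
                                     np.full((32, 32), 5.0))
        assert not t.converged
        assert t.is_identity()


class TestRefineAffine:
    def test_identity_stays_identity(self, blob_scene):
        init = AffineTransform2D.identity(center_of(blob_scene))
        t = refine_affine(blob_scene, blob_scene, init)
        assert np.allclose(t.linear, np.eye(2), atol=1e-3)
        assert np.linalg.norm(t.offset) <= 0.05

    def test_rotation_recovered(self, blob_scene):
        # oracle: grid search over rotation angle minimizing mean_squares
        c = center_of(blob_scene)
        theta = np.deg2rad(2.0)
        rot = AffineTransform2D(
            np.array([[np.cos(theta), -np.sin(theta)],
                      [np.sin(theta), np.cos(theta)]]), np.zeros(2), c)
        moving = apply_transform(blob_scene, rot.inverse(), cval=100.0)

        def ms_at_angle(deg):
            a = np.deg2rad(deg)
            t = AffineTransform2D(np.array([[np.cos(a), -np.sin(a)],
                                            [np.sin(a), np.cos(a)]]),
                                  np.zeros(2), c)
            return mean_squares(blob_scene,
                                apply_transform(moving, t, cval=np.nan))

        grid = np.arange(0.0, 4.01, 0.25)
        oracle_deg = grid[np.argmin([ms_at_angle(g) for g in grid])]
        assert oracle_deg == pytest.approx(2.0, abs=0.25)

        t = refine_affine(blob_scene, moving,
                          AffineTransform2D.identity(c))
        est_deg = np.degrees(np.arctan2(t.linear[1, 0], t.linear[0, 0]))
        assert est_deg == pytest.approx(2.0, abs=0.25)

    def test_scale_recovered(self, blob_scene):
        c = center_of(blob_scene)
        sc = AffineTransform2D(np.eye(2) / 1.03, np.zeros(2), c)
        moving = apply_transform(blob_scene, sc, cval=100.0)
        t = refine_affine(blob_scene, moving, AffineTransform2D.identity(c))
        est_scale = np.sqrt(np.linalg.det(t.linear))
        assert est_scale == pytest.approx(1.03, abs=0.01)

    def test_metric_never_worse_than_init(self, blob_scene):
        moving = shift_scene(blob_scene, (2.0, 1.0))
        init = AffineTransform2D.identity(center_of(blob_scene))
        t = refine_affine(blob_scene, moving, init)
        ms_init = mean_squares(blob_scene,
                               apply_transform(moving, init, cval=np.nan))
        ms_final = mean_squares(blob_scene,
                                apply_transform(moving, t, cval=np.nan))
        assert ms_final <= ms_init


class TestRegisterStack:
    def test_motionless_movie_identity(self):
        spec = SynthMovieSpec(n_frames=4, n_cells=8, responder_fraction=0.0,
                              motion_model="none", noise_sd=0.0, seed=2)
        movie, _ = generate_movie(spec, make_electrical_train(
            n_rounds=1, pulses_per_round=1, start_s=0.2))
        reg, transforms = register_stack(movie)
        for t in transforms:
            assert np.allclose(t.linear, np.eye(2), atol=1e-3)
            assert np.linalg.norm(t.offset) <= 0.05
        assert np.allclose(reg.frames, movie.frames, atol=1e-6)

    def test_known_translations_recovered(self):
        spec = SynthMovieSpec(n_frames=20, n_cells=10,
                              responder_fraction=0.0,
                              motion_model="translation", noise_sd=1.0,
                              seed=5)
        movie, truth = generate_movie(spec, make_electrical_train(
            n_rounds=1, pulses_per_round=1, start_s=0.5))
        reg, transforms = register_stack(movie, reference="first_frame")
        true = np.array([t.offset for t in truth.true_motion])
        est = np.array([t.offset for t in transforms])
        resid = est + true  # registration recovers the inverse shift
        resid = resid - resid[0]  # relative to the reference frame
        assert np.sqrt((resid ** 2).mean()) < 0.5

    def test_concatenated_segments_equal_single_run(self):
        spec = SynthMovieSpec(n_frames=12, n_cells=10,
                              responder_fraction=0.0,
                              motion_model="translation", noise_sd=0.5,
                              seed=9)
        movie, _ = generate_movie(spec, make_electrical_train(
            n_rounds=1, pulses_per_round=1, start_s=0.5))
        reg_full, t_full = register_stack(movie, reference="first_frame")
        # same frames packaged as a concatenation of two segments
        concat = MovieStack(np.concatenate([movie.frames[:6],
                                            movie.frames[6:]]),
                            movie.frame_rate_hz, movie.pixel_size_um)
        reg_cat, t_cat = register_stack(concat, reference="first_frame")
        assert np.allclose(reg_full.frames, reg_cat.frames)
        for a, b in zip(t_full, t_cat):
            assert np.allclose(a.offset, b.offset)

    def test_composition_consistency(self, blob_scene):
        moving = shift_scene(blob_scene, (2.0, -1.0))
        t1 = estimate_translation(blob_scene, moving)
        pre_shifted = shift_scene(moving, (3.0, 2.0))
        t2 = estimate_translation(blob_scene, pre_shifted)
        assert np.linalg.norm(t2.offset - (t1.offset + (3.0, 2.0))) < 0.5

    def test_single_frame_rejected(self):
        movie = MovieStack(np.random.default_rng(0).random((1, 16, 16)))
        with pytest.raises(ValueError):
            register_stack(movie)


class TestOptimizerConfig:
    def test_invalid_steps_rejected(self):
        with pytest.raises(ValueError):
            OptimizerConfig(initial_step=0.001, min_step=0.01)
        with pytest.raises(ValueError):
            OptimizerConfig(max_iterations=0)
        with pytest.raises(ValueError):
            OptimizerConfig(relaxation=1.5)


class TestTransformAlgebra:
    def test_compose_matches_sequential_mapping(self):
        rng = np.random.default_rng(3)
        a = AffineTransform2D(np.eye(2) + 0.05 * rng.normal(size=(2, 2)),
                              rng.normal(size=2), rng.normal(size=2))
        b = AffineTransform2D(np.eye(2) + 0.05 * rng.normal(size=(2, 2)),
                              rng.normal(size=2), rng.normal(size=2))
        pts = rng.normal(size=(5, 2)) * 10
        assert np.allclose(a.compose(b).map_points(pts),
                           a.map_points(b.map_points(pts)))

    def test_inverse_round_trip(self):
        t = AffineTransform2D(np.array([[1.1, 0.1], [0.0, 0.9]]),
                              np.array([3.0, -2.0]), np.array([8.0, 8.0]))
        pts = np.array([[1.0, 2.0], [5.0, 5.0]])
        assert np.allclose(t.inverse().map_points(t.map_points(pts)), pts)

    def test_json_round_trip(self):
        t = AffineTransform2D(np.array([[1.1, 0.0], [0.0, 0.9]]),
                              np.array([1.0, 2.0]), np.array([4.0, 4.0]))
        t2 = AffineTransform2D.from_dict(t.to_dict())
        assert np.allclose(t2.linear, t.linear)
        assert np.allclose(t2.offset, t.offset)
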