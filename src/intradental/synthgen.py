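"""Synthetic input generators with exported ground truth.

Every downstream stage of the package is testable against these artifacts:
fluorescence movies with GCaMP-like stimulus-entrained transients, diffuse
neuropil contamination and per-frame rigid/affine motion; guidepost image
pairs related by a known smooth non-rigid warp; EMG traces with band-limited
reflex bursts at known latency and amplitude; two-keypoint jaw tracks with
programmed deflections; and two-channel immune-stain images.

All generators are deterministic: equal seed and parameters produce
bit-identical outputs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .classify import StimulusTrain
from .fluor import ROI, ROISet
from .ishreg import PolynomialWarp2, WarpModel, _sample_grid
from .motion import AffineTransform2D, MovieStack, apply_transform
from .reflex import EMGTrace, KeypointTrack, TriggerTrace


@dataclass
class GroundTruth:
    """Generative values paired with a synthetic artifact."""

    true_cell_centers: np.ndarray | None = None
    true_rois: ROISet | None = None
    true_responder_labels: np.ndarray | None = None  # n_cells x n_rounds
    true_motion: list | None = None  # per-frame AffineTransform2D applied
    true_transient_amplitudes: np.ndarray | None = None
    true_warp: WarpModel | None = None
    true_control_points: np.ndarray | None = None  # n x 2 x 2 (fixed, moving)
    true_positivity: np.ndarray | None = None  # n_cells x n_marker_channels
    true_reflex: dict | None = None
    true_deflection_um: float | None = None
    true_masks: dict | None = None
    extras: dict = field(default_factory=dict)


@dataclass
class SynthMovieSpec:
    height_px: int = 128
    width_px: int = 128
    n_frames: int = 200
    frame_rate_hz: float = 5.0
    pixel_size_um: float = 2.0
    n_cells: int = 20
    cell_diameter_um_range: tuple = (7.0, 52.0)
    responder_fraction: float = 0.5
    transient_amplitude: float = 20.0
    transient_decay_s: float = 0.4
    neuropil_amplitude: float = 0.0
    motion_model: str = "none"  # none | translation | affine
    motion_max_translation_px: float = 8.0
    motion_max_rotation_deg: float = 3.0
    noise_sd: float = 0.0
    background: float = 100.0
    cell_baseline: float = 50.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.height_px <= 0 or self.width_px <= 0 or self.n_frames < 1:
            raise ValueError("dimensions and n_frames must be positive")
        if not (0.0 <= self.responder_fraction <= 1.0):
            raise ValueError("responder_fraction must lie in [0, 1]")
        lo, hi = self.cell_diameter_um_range
        if lo <= 0 or hi < lo:
            raise ValueError("cell diameters must be positive with low <= high")
        if self.motion_model not in ("none", "translation", "affine"):
            raise ValueError("motion_model must be none|translation|affine")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def _place_centers(rng: np.random.Generator, n: int, shape: tuple,
                   radii_px: np.ndarray, margin: float) -> np.ndarray:
    """Rejection-sample cell centers with non-overlap and an edge margin."""
    h, w = shape
    centers: list = []
    for i in range(n):
        r = radii_px[i]
        lo_r, hi_r = margin + r, h - margin - r
        lo_c, hi_c = margin + r, w - margin - r
        if lo_r >= hi_r or lo_c >= hi_c:
            raise ValueError("image too small for the requested cells")
        for _ in range(500):
            cand = np.array([rng.uniform(lo_r, hi_r), rng.uniform(lo_c, hi_c)])
            ok = all(np.linalg.norm(cand - c) > r + radii_px[j] + 3
                     for j, c in enumerate(centers))
            if ok:
                centers.append(cand)
                break
        else:
            raise ValueError("could not place cells without overlap; "
                             "reduce n_cells or diameters")
    return np.array(centers).reshape(n, 2)


def _render_blobs(shape: tuple, centers: np.ndarray, sigmas: np.ndarray,
                  amplitudes: np.ndarray, truncate_sigmas: float = 2.0
                  ) -> np.ndarray:
    """Sum of isotropic Gaussian blobs truncated at ``truncate_sigmas``."""
    img = np.zeros(shape)
    for (cr, cc), s, a in zip(centers, sigmas, amplitudes):
        rad = truncate_sigmas * s
        r0, r1 = max(0, int(np.floor(cr - rad))), min(shape[0], int(np.ceil(cr + rad)) + 1)
        c0, c1 = max(0, int(np.floor(cc - rad))), min(shape[1], int(np.ceil(cc + rad)) + 1)
        rr, cc2 = np.meshgrid(np.arange(r0, r1), np.arange(c0, c1),
                              indexing="ij")
        d2 = (rr - cr) ** 2 + (cc2 - cc) ** 2
        blob = a * np.exp(-d2 / (2.0 * s * s))
        blob[d2 > rad * rad] = 0.0
        img[r0:r1, c0:c1] += blob
    return img


def _disc_masks(shape: tuple, centers: np.ndarray,
                radii_px: np.ndarray) -> list:
    masks = []
    rr, cc = np.meshgrid(np.arange(shape[0]), np.arange(shape[1]),
                         indexing="ij")
    for (cr, c0), rad in zip(centers, radii_px):
        masks.append((rr - cr) ** 2 + (cc - c0) ** 2 <= rad * rad)
    return masks


def _transient_kernel(t: np.ndarray, onsets_s: np.ndarray,
                      decay_s: float) -> np.ndarray:
    """Instant rise at each onset, single-exponential decay; sums over pulses."""
    out = np.zeros_like(t)
    for on in onsets_s:
        # small tolerance so frame-aligned onsets are not missed to fp error
        active = t >= on - 1e-9
        out[active] += np.exp(-np.maximum(t[active] - on, 0.0) / decay_s)
    return out


def _smooth_walk(rng: np.random.Generator, n: int, step_sd: float,
                 clamp: float, smooth_sigma: float = 3.0,
                 anchor_first: bool = False) -> np.ndarray:
    walk = np.cumsum(rng.normal(0.0, step_sd, size=n))
    walk = ndimage.gaussian_filter1d(walk, smooth_sigma)
    if anchor_first:
        walk = walk - walk[0]  # frame 0 carries zero motion
    return np.clip(walk, -clamp, clamp)


def make_electrical_train(n_rounds: int = 3, pulses_per_round: int = 5,
                          rate_hz: float = 0.6, pulse_duration_s: float = 0.2,
                          start_s: float = 8.0, inter_round_gap_s: float = 5.0
                          ) -> StimulusTrain:
    """Electrical pulse train grouped into rounds (0.6 Hz, 200 ms pulses)."""
    onsets, rounds = [], []
    round_span = pulses_per_round / rate_hz + inter_round_gap_s
    for r in range(n_rounds):
        base = start_s + r * round_span
        onsets.extend(base + np.arange(pulses_per_round) / rate_hz)
        rounds.extend([r] * pulses_per_round)
    return StimulusTrain("electrical", np.array(onsets), pulse_duration_s,
                         np.array(rounds),
                         {"rate_hz": rate_hz, "voltage_v": (2, 4),
                          "duty": 0.12})


def generate_movie(spec: SynthMovieSpec, stim: StimulusTrain
                   ) -> tuple[MovieStack, GroundTruth]:
    """Synthetic fluorescence movie with full generative ground truth.

    Responder cells emit one transient per pulse (instant rise, exponential
    decay), added uniformly over the cell's ROI mask so that the
    neuropil-corrected soma-mean trace peaks at ``transient_amplitude``.  A
    zero-spatial-mean smooth neuropil field (sigma 30 px), per-frame motion,
    and i.i.d. Gaussian noise are then applied.
    """
    duration_s = spec.n_frames / spec.frame_rate_hz
    if stim.pulse_onsets_s.size and stim.pulse_onsets_s.max() >= duration_s:
        raise ValueError("stimulus onsets exceed the recording duration")
    rng = np.random.default_rng(spec.seed)
    shape = (spec.height_px, spec.width_px)

    diam_um = rng.uniform(*spec.cell_diameter_um_range, size=spec.n_cells)
    diam_px = diam_um / spec.pixel_size_um
    radii_px = diam_px / 2.0
    sigmas = diam_px / 4.0
    margin = spec.motion_max_translation_px + 2 if spec.motion_model != "none" else 1
    centers = _place_centers(rng, spec.n_cells, shape, radii_px, margin)

    n_resp = int(round(spec.responder_fraction * spec.n_cells))
    responder = np.zeros(spec.n_cells, dtype=bool)
    if n_resp:
        responder[rng.choice(spec.n_cells, size=n_resp, replace=False)] = True
    rounds = stim.rounds if stim.pulse_onsets_s.size else [0]
    labels = np.zeros((spec.n_cells, len(rounds)), dtype=bool)
    labels[responder, :] = True
    amplitudes = np.where(responder, spec.transient_amplitude, 0.0)

    static = spec.background + _render_blobs(
        shape, centers, sigmas, np.full(spec.n_cells, spec.cell_baseline))
    masks = _disc_masks(shape, centers, radii_px)
    # transient footprint extends slightly past the ROI so that resampling
    # during motion/registration does not erode the mask-mean amplitude
    transient_masks = _disc_masks(shape, centers, radii_px + 1.5)
    rois = ROISet([ROI(f"cell{i:03d}", m) for i, m in enumerate(masks)], shape)

    t = np.arange(spec.n_frames) / spec.frame_rate_hz
    kernel = (_transient_kernel(t, stim.pulse_onsets_s, spec.transient_decay_s)
              if stim.pulse_onsets_s.size else np.zeros_like(t))

    if spec.neuropil_amplitude > 0:
        field_img = ndimage.gaussian_filter(rng.standard_normal(shape), 30.0)
        field_img -= field_img.mean()
        rms = float(np.sqrt(np.mean(field_img**2)))
        field_img /= max(rms, 1e-12)
        np_scale = spec.neuropil_amplitude * (
            1.0 + 0.1 * _smooth_walk(rng, spec.n_frames, 0.2, 1.0))
    else:
        field_img = np.zeros(shape)
        np_scale = np.zeros(spec.n_frames)

    transforms: list[AffineTransform2D] = []
    center = np.array([(shape[0] - 1) / 2.0, (shape[1] - 1) / 2.0])
    if spec.motion_model == "none":
        transforms = [AffineTransform2D.identity(center)
                      for _ in range(spec.n_frames)]
    else:
        dr = _smooth_walk(rng, spec.n_frames, 0.8,
                          spec.motion_max_translation_px, anchor_first=True)
        dc = _smooth_walk(rng, spec.n_frames, 0.8,
                          spec.motion_max_translation_px, anchor_first=True)
        if spec.motion_model == "translation":
            for k in range(spec.n_frames):
                transforms.append(AffineTransform2D(
                    np.eye(2), np.array([dr[k], dc[k]]), center))
        else:
            ang = np.deg2rad(_smooth_walk(rng, spec.n_frames, 0.3,
                                          spec.motion_max_rotation_deg,
                                          anchor_first=True))
            for k in range(spec.n_frames):
                c, s = np.cos(ang[k]), np.sin(ang[k])
                transforms.append(AffineTransform2D(
                    np.array([[c, -s], [s, c]]),
                    np.array([dr[k], dc[k]]), center))

    frames = np.empty((spec.n_frames,) + shape)
    roi_stack = np.zeros(shape)
    for k in range(spec.n_frames):
        scene = static + np_scale[k] * field_img
        if kernel[k] > 0:
            roi_stack[:] = 0.0
            for i in np.flatnonzero(responder):
                roi_stack[transient_masks[i]] += amplitudes[i] * kernel[k]
            scene = scene + roi_stack
        frame = (scene if transforms[k].is_identity()
                 else apply_transform(scene, transforms[k],
                                      cval=spec.background))
        frames[k] = frame
    if spec.noise_sd > 0:
        frames += rng.normal(0.0, spec.noise_sd, size=frames.shape)

    movie = MovieStack(frames, spec.frame_rate_hz, spec.pixel_size_um)
    truth = GroundTruth(
        true_cell_centers=centers,
        true_rois=rois,
        true_responder_labels=labels,
        true_motion=transforms,
        true_transient_amplitudes=amplitudes,
        extras={"diameter_um": diam_um, "transient_kernel": kernel,
                "responder": responder, "spec": spec, "stim": stim},
    )
    return movie, truth


def generate_ish_pair(height_px: int = 160, width_px: int = 160,
                      n_guideposts: int = 10, n_channels: int = 3,
                      warp_magnitude_px: float = 3.0, seed: int = 0,
                      n_cells: int = 20, poly_warp: PolynomialWarp2 | None = None,
                      noise_sd: float = 0.0, warp_smooth_sigma_px: float = 40.0
                      ) -> tuple[np.ndarray, np.ndarray, GroundTruth]:
    """Guidepost image pair related by a known smooth non-rigid warp.

    Returns ``(fixed_image, moving_stack, truth)``.  The fixed image is the
    guidepost channel on the reference grid; the moving stack has the
    guidepost channel first, then ``n_channels - 1`` marker channels with
    known per-cell positivity.  The true warp maps fixed coordinates to
    moving coordinates as polynomial-then-displacement; the moving images
    are rendered by sampling the fixed-grid scene through the inverted warp.
    """
    if n_guideposts < 6:
        raise ValueError("need >= 6 guideposts for a second-order "
                         "polynomial fit")
    if warp_magnitude_px < 0:
        raise ValueError("warp_magnitude_px must be >= 0")
    if n_channels < 1:
        raise ValueError("need at least the guidepost channel")
    rng = np.random.default_rng(seed)
    shape = (height_px, width_px)
    n_total = n_guideposts + n_cells
    radii = rng.uniform(3.0, 6.0, size=n_total)
    centers = _place_centers(rng, n_total, shape, radii,
                             margin=10 + warp_magnitude_px)
    sigmas = radii / 2.0

    guide_amp = np.zeros(n_total)
    guide_amp[:n_guideposts] = rng.uniform(150.0, 250.0, size=n_guideposts)
    fixed_channels = [np.full(shape, 10.0) + _render_blobs(
        shape, centers, sigmas, guide_amp)]
    positivity = np.zeros((n_total, max(0, n_channels - 1)), dtype=bool)
    for ch in range(n_channels - 1):
        pos = rng.random(n_total) < 0.5
        positivity[:, ch] = pos
        amp = np.where(pos, rng.uniform(120.0, 200.0, size=n_total), 0.0)
        fixed_channels.append(np.full(shape, 10.0) + _render_blobs(
            shape, centers, sigmas, amp))

    if poly_warp is None:
        # gentle non-identity quadratic: a few px of translation plus
        # curvature reaching ~3 px at the image corners
        q = 3.0 / (max(shape) ** 2)
        poly_warp = PolynomialWarp2(
            [2.0, 1.0, 0.004, q, 0.0, -q],
            [-1.5, -0.003, 1.0, -q, 0.5 * q, q])
    if warp_magnitude_px > 0:
        disp = np.stack(
            [ndimage.gaussian_filter(rng.standard_normal(shape),
                                     warp_smooth_sigma_px) for _ in range(2)],
            axis=-1)
        rms = float(np.sqrt(np.mean(np.sum(disp**2, axis=-1))))
        disp *= warp_magnitude_px / max(rms, 1e-12)
    else:
        disp = np.zeros(shape + (2,))
    truth_warp = WarpModel(poly_warp, disp, shape)

    if truth_warp.is_identity():
        moving_stack = np.stack([ch.copy() for ch in fixed_channels])
    else:
        grid = _sample_grid(shape).reshape(-1, 2)
        src = truth_warp.invert_points(grid)
        coords = src.T.reshape(2, *shape)
        moving_stack = np.stack([
            ndimage.map_coordinates(ch, coords, order=1, mode="nearest")
            for ch in fixed_channels])
    fixed = fixed_channels[0]
    if noise_sd > 0:
        fixed = fixed + rng.normal(0.0, noise_sd, size=fixed.shape)
        moving_stack = moving_stack + rng.normal(0.0, noise_sd,
                                                 size=moving_stack.shape)

    guide_fixed = centers[:n_guideposts]
    guide_moving = truth_warp.map_points(guide_fixed)
    rois = ROISet([ROI(f"cell{i:03d}", m) for i, m in enumerate(
        _disc_masks(shape, centers, radii))], shape)
    truth = GroundTruth(
        true_cell_centers=centers,
        true_rois=rois,
        true_warp=truth_warp,
        true_control_points=np.stack([guide_fixed, guide_moving], axis=1),
        true_positivity=positivity[:, :] if n_channels > 1 else None,
        extras={"n_guideposts": n_guideposts, "radii_px": radii},
    )
    return fixed, moving_stack, truth


def generate_emg(sample_rate_hz: float = 20000.0,
                 stim_onsets_s=(0.5,), latency_s: float = 0.008,
                 burst_duration_s: float = 0.03,
                 peak_to_peak_mv: float = 1.0, noise_sd_mv: float = 0.0,
                 seed: int = 0, duration_s: float | None = None,
                 carrier_hz: float = 1000.0) -> tuple[EMGTrace, GroundTruth]:
    """EMG trace with a band-limited reflex burst after each stimulus.

    The burst is a sine carrier (inside the 100-3000 Hz pass band) starting
    ``latency_s`` after each stimulus onset, lasting ``burst_duration_s``,
    with the requested peak-to-peak amplitude, plus optional Gaussian noise.
    """
    if sample_rate_hz < 6000:
        raise ValueError("sample_rate_hz must be >= 6000")
    if latency_s < 0:
        raise ValueError("latency_s must be >= 0")
    onsets = np.asarray(stim_onsets_s, dtype=float)
    if duration_s is None:
        tail = latency_s + burst_duration_s + 0.2
        duration_s = (float(onsets.max()) + tail) if onsets.size else 1.0
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * sample_rate_hz))
    t = np.arange(n) / sample_rate_hz
    samples = np.zeros(n)
    amp = peak_to_peak_mv / 2.0
    for on in onsets:
        t0 = on + latency_s
        sel = (t >= t0) & (t < t0 + burst_duration_s)
        samples[sel] += amp * np.sin(2.0 * np.pi * carrier_hz * (t[sel] - t0))
    if noise_sd_mv > 0:
        samples += rng.normal(0.0, noise_sd_mv, size=n)
    trace = EMGTrace(samples, sample_rate_hz, onsets)
    truth = GroundTruth(true_reflex={
        "latency_s": latency_s, "burst_duration_s": burst_duration_s,
        "peak_to_peak_mv": peak_to_peak_mv, "carrier_hz": carrier_hz})
    return trace, truth


def generate_jaw_track(video_rate_hz: float = 170.0,
                       trigger_rate_hz: float = 10000.0,
                       pulse_onsets_s=(1.0,), deflection_um: float = 305.0,
                       deflection_duration_s: float = 1.0,
                       px_per_um: float = 0.5, noise_sd_px: float = 0.0,
                       seed: int = 0, duration_s: float | None = None,
                       baseline_distance_px: float = 120.0
                       ) -> tuple[KeypointTrack, GroundTruth]:
    """Two-keypoint incisor track with programmed deflections.

    The inter-incisor Euclidean distance increases by ``deflection_um``
    (converted to px) for ``deflection_duration_s`` after each trigger
    pulse; Gaussian jitter of sd ``noise_sd_px`` is added to every
    coordinate.
    """
    if video_rate_hz <= 0 or trigger_rate_hz <= 0:
        raise ValueError("rates must be positive")
    if trigger_rate_hz < video_rate_hz:
        raise ValueError("trigger rate must be >= video rate")
    onsets = np.asarray(pulse_onsets_s, dtype=float)
    if duration_s is None:
        duration_s = float(onsets.max()) + deflection_duration_s + 1.0
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * video_rate_hz))
    t = np.round(np.arange(n) / video_rate_hz * trigger_rate_hz) / trigger_rate_hz
    defl_px = deflection_um * px_per_um
    d = np.full(n, baseline_distance_px)
    for on in onsets:
        d[(t >= on) & (t < on + deflection_duration_s)] += defl_px
    top = np.column_stack([np.full(n, 50.0), np.full(n, 40.0)])
    bottom = np.column_stack([np.full(n, 50.0), 40.0 + d])
    if noise_sd_px > 0:
        top = top + rng.normal(0.0, noise_sd_px, size=top.shape)
        bottom = bottom + rng.normal(0.0, noise_sd_px, size=bottom.shape)
    track = KeypointTrack(top, bottom, video_rate_hz, px_per_um,
                          TriggerTrace(trigger_rate_hz, onsets))
    truth = GroundTruth(true_deflection_um=deflection_um,
                        extras={"baseline_distance_px": baseline_distance_px,
                                "deflection_px": defl_px})
    return track, truth


def generate_immune_image(height_px: int = 128, width_px: int = 128,
                          n_rois: int = 5, roi_intensity: float = 100.0,
                          background_intensity: float = 10.0,
                          noise_sd: float = 0.0, seed: int = 0
                          ) -> tuple[np.ndarray, GroundTruth]:
    """Two-channel immune image: bright nuclear blobs defining the ROIs and
    a signal channel at ``roi_intensity`` inside them, ``background_intensity``
    outside."""
    if n_rois < 0:
        raise ValueError("n_rois must be >= 0")
    if roi_intensity < 0 or background_intensity < 0:
        raise ValueError("intensities must be >= 0")
    rng = np.random.default_rng(seed)
    shape = (height_px, width_px)
    if n_rois:
        radii = rng.uniform(8.0, 14.0, size=n_rois)
        centers = _place_centers(rng, n_rois, shape, radii, margin=4)
        masks = _disc_masks(shape, centers, radii)
        roi_mask = np.zeros(shape, dtype=bool)
        for m in masks:
            roi_mask |= m
    else:
        roi_mask = np.zeros(shape, dtype=bool)
    nuclear = np.where(roi_mask, 200.0, 20.0)
    sig = np.where(roi_mask, roi_intensity, background_intensity)
    if noise_sd > 0:
        nuclear = nuclear + rng.normal(0.0, noise_sd, size=shape)
        sig = sig + rng.normal(0.0, noise_sd, size=shape)
    image = np.stack([nuclear, sig])
    truth = GroundTruth(true_masks={"roi": roi_mask},
                        extras={"roi_intensity": roi_intensity,
                                "background_intensity": background_intensity})
    return image, truth
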