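"""Region-level immune-cell fluorescence quantification.

Nuclear-channel thresholding defines the ROIs; morphological cleanup removes
small objects and fills holes; brightness is background-subtracted (scalar
non-ROI mean, optional noise-channel subtraction) and normalized by ROI area.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import filters, morphology


@dataclass
class QuantConfig:
    threshold_method: str | float = "otsu"
    min_object_px: int = 50
    fill_holes: bool = True
    noise_channel_threshold: str | float = "otsu"
    noise_mode: str = "subtract"  # or "mask": zero out noisy pixels instead
    exclusion_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.min_object_px < 0:
            raise ValueError("min_object_px must be >= 0")
        if self.noise_mode not in ("subtract", "mask"):
            raise ValueError("noise_mode must be 'subtract' or 'mask'")


def _threshold(image: np.ndarray, method) -> np.ndarray:
    if method == "otsu":
        return image > filters.threshold_otsu(image)
    return image > float(method)


def segment_rois(nuclear_channel: np.ndarray,
                 cfg: QuantConfig | None = None) -> np.ndarray:
    """Threshold the nuclear channel, remove small objects, fill holes, and
    zero out the exclusion mask.  Raises naming the stage that emptied the
    mask."""
    cfg = cfg or QuantConfig()
    img = np.asarray(nuclear_channel, dtype=float)
    if img.size == 0:
        raise ValueError("empty image")
    if np.ptp(img) == 0:
        raise ValueError("segmentation empty after thresholding: "
                         "nuclear channel is constant")
    mask = _threshold(img, cfg.threshold_method)
    if not mask.any():
        raise ValueError("segmentation empty after thresholding")
    if cfg.min_object_px > 0:
        mask = morphology.remove_small_objects(mask, cfg.min_object_px)
        if not mask.any():
            raise ValueError("segmentation empty after small-object removal")
    if cfg.fill_holes:
        mask = ndimage.binary_fill_holes(mask)
    if cfg.exclusion_mask is not None:
        excl = np.asarray(cfg.exclusion_mask, dtype=bool)
        if excl.shape != mask.shape:
            raise ValueError("exclusion mask shape mismatch")
        mask &= ~excl
        if not mask.any():
            raise ValueError("segmentation empty after exclusion masking")
    return mask


def subtract_background(signal_channel: np.ndarray, roi_mask: np.ndarray,
                        noise_channel: np.ndarray | None = None,
                        cfg: QuantConfig | None = None) -> np.ndarray:
    """Two-stage background subtraction, clamped at zero.

    Subtracts the scalar mean of the signal over non-ROI pixels everywhere;
    where a thresholded noise channel is positive, additionally subtracts
    the noise-channel intensity (or masks those pixels to zero when
    ``noise_mode='mask'``).
    """
    cfg = cfg or QuantConfig()
    sig = np.asarray(signal_channel, dtype=float)
    roi = np.asarray(roi_mask, dtype=bool)
    if sig.shape != roi.shape:
        raise ValueError("signal and ROI mask shapes differ")
    bg = ~roi
    if not bg.any():
        raise ValueError("ROI mask covers the whole image; no background")
    out = sig - float(sig[bg].mean())
    if noise_channel is not None:
        noise = np.asarray(noise_channel, dtype=float)
        if noise.shape != sig.shape:
            raise ValueError("noise channel shape mismatch")
        noisy = _threshold(noise, cfg.noise_channel_threshold)
        if cfg.noise_mode == "subtract":
            out = np.where(noisy, out - noise, out)
        else:
            out = np.where(noisy, 0.0, out)
    return np.clip(out, 0.0, None)


def roi_brightness(corrected_signal: np.ndarray, roi_mask: np.ndarray) -> float:
    """Total corrected fluorescence over the ROIs divided by ROI area."""
    sig = np.asarray(corrected_signal, dtype=float)
    roi = np.asarray(roi_mask, dtype=bool)
    if sig.shape != roi.shape:
        raise ValueError("shape mismatch")
    n = int(roi.sum())
    if n == 0:
        raise ValueError("empty ROI mask")
    return float(sig[roi].sum() / n)


def quantify(image: np.ndarray, cfg: QuantConfig | None = None) -> dict:
    """End-to-end quantification of a (nuclear, signal[, noise]) stack."""
    cfg = cfg or QuantConfig()
    image = np.asarray(image, dtype=float)
    if image.ndim != 3 or image.shape[0] < 2:
        raise ValueError("need a C x H x W stack with >= 2 channels")
    nuclear, signal = image[0], image[1]
    noise = image[2] if image.shape[0] > 2 else None
    mask = segment_rois(nuclear, cfg)
    corrected = subtract_background(signal, mask, noise, cfg)
    return {"roi_mask": mask, "corrected": corrected,
            "roi_area_px": int(mask.sum()),
            "mean_brightness": roi_brightness(corrected, mask)}
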