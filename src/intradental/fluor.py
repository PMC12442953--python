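"""ROI management, neuropil-corrected dF trace extraction, AUC, morphometrics.

Traces are differences of means (soma mean minus local-neuropil mean per
frame), i.e. dF in raw fluorescence units; normalization happens only inside
:func:`compute_auc`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, spatial
from skimage import draw, morphology

from .motion import MovieStack


@dataclass
class ROI:
    id: str
    mask: np.ndarray

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if not self.mask.any():
            raise ValueError(f"ROI {self.id!r} has an empty mask")


def polygon_to_mask(vertices, image_shape) -> np.ndarray:
    """Rasterize a simple polygon: a pixel belongs to the ROI if its center
    lies inside the polygon (even-odd rule).  Vertices are (row, col)."""
    verts = np.asarray(vertices, dtype=float)
    if verts.ndim != 2 or verts.shape[1] != 2 or len(verts) < 3:
        raise ValueError("polygon needs >= 3 (row, col) vertices")
    return draw.polygon2mask(tuple(image_shape), verts)


@dataclass
class ROISet:
    """Labeled regions on a fixed image grid."""

    rois: list
    image_shape: tuple

    def __post_init__(self) -> None:
        self.image_shape = tuple(int(v) for v in self.image_shape)
        parsed = []
        for r in self.rois:
            if isinstance(r, ROI):
                roi = r
            elif isinstance(r, dict):
                if "mask" in r:
                    roi = ROI(str(r["id"]), np.asarray(r["mask"], dtype=bool))
                elif "polygon" in r:
                    roi = ROI(str(r["id"]),
                              polygon_to_mask(r["polygon"], self.image_shape))
                else:
                    raise ValueError("ROI dict needs a 'mask' or 'polygon' key")
            else:
                raise TypeError(f"cannot interpret ROI {r!r}")
            if roi.mask.shape != self.image_shape:
                raise ValueError(
                    f"ROI {roi.id!r} mask shape {roi.mask.shape} != image "
                    f"shape {self.image_shape}")
            parsed.append(roi)
        ids = [r.id for r in parsed]
        if len(set(ids)) != len(ids):
            raise ValueError("ROI ids must be unique")
        self.rois = parsed

    def __len__(self) -> int:
        return len(self.rois)

    def __iter__(self):
        return iter(self.rois)

    @property
    def ids(self) -> list:
        return [r.id for r in self.rois]

    def union_mask(self) -> np.ndarray:
        out = np.zeros(self.image_shape, dtype=bool)
        for r in self.rois:
            out |= r.mask
        return out

    def to_labels(self) -> np.ndarray:
        """Label image: 0 = background, i+1 = i-th ROI (later ROIs win ties)."""
        lab = np.zeros(self.image_shape, dtype=np.int32)
        for i, r in enumerate(self.rois):
            lab[r.mask] = i + 1
        return lab

    @classmethod
    def from_labels(cls, labels: np.ndarray, ids=None) -> "ROISet":
        labels = np.asarray(labels)
        values = [int(v) for v in np.unique(labels) if v != 0]
        if ids is None:
            ids = [str(v) for v in values]
        rois = [ROI(i, labels == v) for i, v in zip(ids, values)]
        return cls(rois, labels.shape)


@dataclass
class NeuropilConfig:
    inner_margin_px: int = 2
    outer_margin_px: int = 8
    exclude_other_somata: bool = True

    def __post_init__(self) -> None:
        if not (0 <= self.inner_margin_px < self.outer_margin_px):
            raise ValueError("require 0 <= inner_margin_px < outer_margin_px")


@dataclass
class TraceMatrix:
    values: np.ndarray  # n_cells x T, dF units
    cell_ids: list
    frame_rate_hz: float = 5.0

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if not np.isfinite(self.values).all():
            raise ValueError("trace values must be finite")
        if len(self.cell_ids) != self.values.shape[0]:
            raise ValueError("cell_ids must match the number of trace rows")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_frames(self) -> int:
        return self.values.shape[1]


@dataclass
class AUCConfig:
    start_frame: int = 40
    end_frame: int = 120
    normalization: str = "df_over_f0"
    baseline_frames: tuple = (0, 39)

    def __post_init__(self) -> None:
        if self.start_frame >= self.end_frame:
            raise ValueError("start_frame must be < end_frame")
        if self.normalization not in ("df_over_f0", "baseline_z", "none"):
            raise ValueError("unknown normalization mode")


def _dilate(mask: np.ndarray, radius: int) -> np.ndarray:
    if radius <= 0:
        return mask.copy()
    return ndimage.binary_dilation(mask, structure=morphology.disk(radius))


def make_neuropil_masks(rois: ROISet, cfg: NeuropilConfig | None = None) -> ROISet:
    """Annulus neuropil mask per soma: pixels between dilations by the inner
    and outer margins, minus every somatic pixel when exclusion is enabled.

    A cell whose annulus is emptied by the exclusions falls back to the
    global background (all pixels outside every soma), with a warning.
    """
    cfg = cfg or NeuropilConfig()
    all_somata = rois.union_mask()
    out = []
    for r in rois:
        annulus = _dilate(r.mask, cfg.outer_margin_px) & ~_dilate(
            r.mask, cfg.inner_margin_px)
        annulus &= ~r.mask
        if cfg.exclude_other_somata:
            annulus &= ~all_somata
        if not annulus.any():
            warnings.warn(
                f"neuropil annulus empty for ROI {r.id!r}; falling back to "
                "global background", stacklevel=2)
            annulus = ~all_somata
            if not annulus.any():
                raise ValueError("no background pixels available for neuropil")
        out.append(ROI(f"{r.id}", annulus))
    return ROISet(out, rois.image_shape)


def extract_traces(movie: MovieStack, rois: ROISet,
                   cfg: NeuropilConfig | None = None,
                   neuropil: ROISet | None = None) -> TraceMatrix:
    """Neuropil-corrected dF traces.

    dF_cell(t) = mean over soma pixels at frame t minus mean over that
    cell's neuropil pixels at frame t.  Any spatially uniform contaminant
    cancels exactly.
    """
    if len(rois) == 0:
        raise ValueError("empty ROISet")
    if rois.image_shape != movie.frames.shape[1:]:
        raise ValueError("ROI grid does not match the movie grid")
    if neuropil is None:
        neuropil = make_neuropil_masks(rois, cfg)
    flat = movie.frames.reshape(movie.n_frames, -1)
    values = np.empty((len(rois), movie.n_frames))
    for i, (soma, npil) in enumerate(zip(rois, neuropil)):
        s_idx = np.flatnonzero(soma.mask.ravel())
        n_idx = np.flatnonzero(npil.mask.ravel())
        values[i] = flat[:, s_idx].mean(axis=1) - flat[:, n_idx].mean(axis=1)
    return TraceMatrix(values, rois.ids, movie.frame_rate_hz)


def _normalize_trace(trace: np.ndarray, cfg: AUCConfig) -> np.ndarray:
    if cfg.normalization == "none":
        return trace
    b0, b1 = cfg.baseline_frames
    base = trace[b0:b1 + 1]
    if base.size == 0:
        raise ValueError("baseline window is empty")
    mu = float(base.mean())
    if cfg.normalization == "df_over_f0":
        if abs(mu) < 1e-12:
            warnings.warn("baseline mean ~ 0; df_over_f0 falls back to "
                          "baseline subtraction", stacklevel=3)
            return trace - mu
        return (trace - mu) / mu
    sd = float(base.std())
    if sd < 1e-12:
        warnings.warn("baseline sd ~ 0 for baseline_z; using machine epsilon",
                      stacklevel=3)
        sd = np.finfo(float).eps
    return (trace - mu) / sd


def compute_auc(trace: np.ndarray, cfg: AUCConfig | None = None) -> float:
    """Total trapezoidal area under the (normalized) trace over frames
    [start_frame, end_frame] inclusive, in frame units.  No peak detection,
    no baseline thresholding."""
    cfg = cfg or AUCConfig()
    trace = np.asarray(trace, dtype=float).ravel()
    if cfg.end_frame >= trace.size or cfg.start_frame < 0:
        raise ValueError("AUC window lies outside the trace")
    norm = _normalize_trace(trace, cfg)
    seg = norm[cfg.start_frame:cfg.end_frame + 1]
    return float(np.trapezoid(seg))


def pulse_peak_amplitude(trace: np.ndarray, onsets_s, frame_rate_hz: float,
                         baseline_frames: tuple = (0, 39),
                         peak_window_frames: int = 3) -> float:
    """Stimulus-locked transient amplitude: mean over pulses of the peak dF
    within ``peak_window_frames`` of each onset, minus the baseline mean.

    Averaging across pulses suppresses single-frame noise that would bias a
    global-maximum estimate upward.
    """
    trace = np.asarray(trace, dtype=float).ravel()
    b0, b1 = baseline_frames
    baseline = float(trace[b0:b1 + 1].mean())
    peaks = []
    for onset in np.asarray(onsets_s, dtype=float):
        f0 = int(round(onset * frame_rate_hz))
        if f0 < 0 or f0 >= trace.size:
            continue
        peaks.append(trace[f0:f0 + peak_window_frames].max())
    if not peaks:
        raise ValueError("no pulse lies within the trace")
    return float(np.mean(peaks) - baseline)


def feret_diameter(mask: np.ndarray, pixel_size_um: float = 1.0) -> float:
    """Maximum caliper distance in micrometres.

    Largest Euclidean distance between boundary-pixel centers plus one pixel
    (measuring across pixel areas), times the pixel size.  A single pixel
    therefore measures one pixel equivalent.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    boundary = mask & ~ndimage.binary_erosion(mask, border_value=0)
    pts = np.column_stack(np.nonzero(boundary)).astype(float)
    if len(pts) == 1:
        return float(pixel_size_um)
    if len(pts) > 3:
        try:
            hull = spatial.ConvexHull(pts)
            pts = pts[hull.vertices]
        except spatial.QhullError:
            pass  # collinear points: fall through to brute force
    d = spatial.distance.pdist(pts)
    return float((d.max() + 1.0) * pixel_size_um)
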