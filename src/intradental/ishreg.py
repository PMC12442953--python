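"""Post hoc ISH image alignment to in vivo guidepost recordings.

Stages: percentile normalization of both images to [0, 1], control-point
second-order polynomial initialization (fixed -> moving coordinates),
multiresolution Demons non-rigid refinement (classic intensity-difference
update with Gaussian field smoothing, coarse-to-fine), application of the
composed warp to every channel of the ISH stack, ROI transfer, and the
labeling efficiency/specificity arithmetic.

Warp composition order is fixed: a fixed-grid point ``x`` maps to the moving
image at ``poly(x) + displacement(x)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import transform as sktransform

from .fluor import ROI, ROISet
from .motion import mean_squares


def normalize_percentiles(image: np.ndarray, p_low: float = 0.1,
                          p_high: float = 99.9) -> np.ndarray:
    """Scale intensities so percentile ``p_low`` maps to 0 and ``p_high``
    maps to 1, clipping the tails.  A constant image yields all zeros with a
    warning."""
    image = np.asarray(image, dtype=float)
    if image.size == 0:
        raise ValueError("empty image")
    lo, hi = np.percentile(image, [p_low, p_high])
    if hi <= lo:
        warnings.warn("degenerate percentile range; returning zeros",
                      stacklevel=2)
        return np.zeros_like(image)
    return np.clip((image - lo) / (hi - lo), 0.0, 1.0)


@dataclass
class ControlPoints:
    """Paired landmarks: ((row, col) in fixed, (row, col) in moving)."""

    fixed: np.ndarray
    moving: np.ndarray

    def __post_init__(self) -> None:
        self.fixed = np.atleast_2d(np.asarray(self.fixed, dtype=float))
        self.moving = np.atleast_2d(np.asarray(self.moving, dtype=float))
        if self.fixed.shape != self.moving.shape or self.fixed.shape[1] != 2:
            raise ValueError("fixed and moving must both be (N, 2) arrays")
        if len(self.fixed) < 6:
            raise ValueError("need >= 6 control-point pairs for a "
                             "second-order polynomial fit")
        if not (np.isfinite(self.fixed).all() and np.isfinite(self.moving).all()):
            raise ValueError("control points must be finite")
        uniq = np.unique(self.fixed, axis=0)
        if len(uniq) != len(self.fixed):
            raise ValueError("duplicated fixed control points")

    def __len__(self) -> int:
        return len(self.fixed)

    @classmethod
    def from_pairs(cls, pairs) -> "ControlPoints":
        pairs = np.asarray(pairs, dtype=float)
        return cls(pairs[:, 0, :], pairs[:, 1, :])

    def to_pairs(self) -> list:
        return [[f.tolist(), m.tolist()] for f, m in zip(self.fixed, self.moving)]


def _poly_basis(points: np.ndarray) -> np.ndarray:
    """Second-order basis {1, r, c, r^2, r*c, c^2} for (N, 2) points."""
    r, c = points[:, 0], points[:, 1]
    return np.column_stack([np.ones_like(r), r, c, r * r, r * c, c * c])


IDENTITY_COEFFS_ROW = np.array([0.0, 1.0, 0.0, 0.0, 0.0, 0.0])
IDENTITY_COEFFS_COL = np.array([0.0, 0.0, 1.0, 0.0, 0.0, 0.0])


@dataclass
class PolynomialWarp2:
    """Second-order polynomial map from fixed to moving coordinates."""

    coeffs_row: np.ndarray = field(
        default_factory=lambda: IDENTITY_COEFFS_ROW.copy())
    coeffs_col: np.ndarray = field(
        default_factory=lambda: IDENTITY_COEFFS_COL.copy())

    def __post_init__(self) -> None:
        self.coeffs_row = np.asarray(self.coeffs_row, dtype=float).reshape(6)
        self.coeffs_col = np.asarray(self.coeffs_col, dtype=float).reshape(6)
        if not (np.isfinite(self.coeffs_row).all()
                and np.isfinite(self.coeffs_col).all()):
            raise ValueError("polynomial coefficients must be finite")

    def is_identity(self) -> bool:
        return bool(np.array_equal(self.coeffs_row, IDENTITY_COEFFS_ROW)
                    and np.array_equal(self.coeffs_col, IDENTITY_COEFFS_COL))

    def map_points(self, points: np.ndarray) -> np.ndarray:
        b = _poly_basis(np.atleast_2d(np.asarray(points, dtype=float)))
        return np.column_stack([b @ self.coeffs_row, b @ self.coeffs_col])


def fit_polynomial_warp(points: ControlPoints) -> PolynomialWarp2:
    """Least-squares fit of the moving coordinates on the second-order basis
    of the fixed coordinates; exact on consistent (noiseless) points."""
    design = _poly_basis(points.fixed)
    rank = np.linalg.matrix_rank(design)
    if rank < 6:
        raise ValueError(
            "control-point design matrix is rank deficient (rank "
            f"{rank} < 6): fixed points lie on a conic or coincide")
    sol, *_ = np.linalg.lstsq(design, points.moving, rcond=None)
    return PolynomialWarp2(sol[:, 0], sol[:, 1])


@dataclass
class DemonsConfig:
    n_levels: int = 4
    iterations_per_level: tuple = (5, 1, 1, 1)  # coarse -> fine
    downsample_factor: float = 2.0
    smoothing_sigma_px: float = 1.5

    def __post_init__(self) -> None:
        self.iterations_per_level = tuple(int(i) for i in
                                          self.iterations_per_level)
        if len(self.iterations_per_level) != self.n_levels:
            raise ValueError("iterations_per_level length must equal n_levels")
        if any(i < 1 for i in self.iterations_per_level):
            raise ValueError("iterations must be >= 1 at every level")
        if self.downsample_factor <= 1:
            raise ValueError("downsample_factor must exceed 1")


@dataclass
class WarpModel:
    """Composed non-rigid warp: ``x -> polynomial(x) + displacement[x]``.

    The displacement field lives on the fixed grid in pixels and is applied
    additively after the polynomial.
    """

    polynomial: PolynomialWarp2
    displacement: np.ndarray  # H x W x 2
    fixed_shape: tuple
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.displacement = np.asarray(self.displacement, dtype=float)
        self.fixed_shape = tuple(int(v) for v in self.fixed_shape)
        if self.displacement.shape != self.fixed_shape + (2,):
            raise ValueError("displacement must be H x W x 2 on the fixed grid")
        if not np.isfinite(self.displacement).all():
            raise ValueError("displacement must be finite")

    @classmethod
    def identity(cls, shape) -> "WarpModel":
        shape = tuple(shape)
        return cls(PolynomialWarp2(), np.zeros(shape + (2,)), shape)

    def is_identity(self) -> bool:
        return self.polynomial.is_identity() and not self.displacement.any()

    def map_points(self, points: np.ndarray) -> np.ndarray:
        """Map fixed-grid points into the moving image: polynomial then
        bilinear lookup of the displacement at the *fixed* location."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        poly = self.polynomial.map_points(pts)
        coords = pts.T  # displacement indexed at fixed coords
        d = np.column_stack([
            ndimage.map_coordinates(self.displacement[..., 0], coords,
                                    order=1, mode="nearest"),
            ndimage.map_coordinates(self.displacement[..., 1], coords,
                                    order=1, mode="nearest"),
        ])
        return poly + d

    def invert_points(self, points: np.ndarray, n_iter: int = 20) -> np.ndarray:
        """Map moving-grid points back to the fixed grid by fixed-point
        iteration (accurate for smooth, near-identity-Jacobian warps)."""
        y = np.atleast_2d(np.asarray(points, dtype=float))
        x = y.copy()
        for _ in range(n_iter):
            x = x + (y - self.map_points(x))
        return x


def _sample_grid(shape) -> np.ndarray:
    rr, cc = np.meshgrid(np.arange(shape[0], dtype=float),
                         np.arange(shape[1], dtype=float), indexing="ij")
    return np.stack([rr, cc], axis=-1)  # H x W x 2


def _warp_image(moving: np.ndarray, coords: np.ndarray, order: int = 1,
                cval: float = 0.0) -> np.ndarray:
    """Sample ``moving`` at ``coords`` (H x W x 2)."""
    return ndimage.map_coordinates(
        moving, [coords[..., 0], coords[..., 1]], order=order,
        mode="constant", cval=cval)


def _is_normalized(image: np.ndarray) -> bool:
    return bool(image.min() >= 0.0 and image.max() <= 1.0 and image.max() > 0)


def demons_refine(fixed: np.ndarray, moving: np.ndarray,
                  init: PolynomialWarp2 | None = None,
                  cfg: DemonsConfig | None = None) -> WarpModel:
    """Multiresolution classic Demons refinement of a polynomial warp.

    Both images are percentile-normalized internally if they are not already
    in [0, 1].  The update is the Thirion intensity-difference force driven
    by the fixed-image gradient, with Gaussian smoothing of the displacement
    field after every iteration, run coarse-to-fine with the configured
    iteration schedule.  The result never worsens the mean-squares metric
    relative to the polynomial-only initialization; if no improvement is
    possible the initialization is returned with zero displacement and a
    warning.
    """
    cfg = cfg or DemonsConfig()
    init = init or PolynomialWarp2()
    fixed = np.asarray(fixed, dtype=float)
    moving = np.asarray(moving, dtype=float)
    if not _is_normalized(fixed):
        fixed = normalize_percentiles(fixed)
    if not _is_normalized(moving):
        moving = normalize_percentiles(moving)
    shape = fixed.shape
    grid = _sample_grid(shape)

    # resample the moving image through the polynomial once; demons then
    # estimates a residual displacement u on the fixed grid
    poly_coords = init.map_points(grid.reshape(-1, 2)).reshape(shape + (2,))
    moving_poly = _warp_image(moving, poly_coords)
    ms_init = mean_squares(fixed, moving_poly)

    factor = cfg.downsample_factor
    pyramid_f, pyramid_m = [fixed], [moving_poly]
    for _ in range(cfg.n_levels - 1):
        pyramid_f.append(sktransform.rescale(pyramid_f[-1], 1.0 / factor,
                                             anti_aliasing=True))
        pyramid_m.append(sktransform.rescale(pyramid_m[-1], 1.0 / factor,
                                             anti_aliasing=True))
    pyramid_f.reverse()
    pyramid_m.reverse()

    def _upsample(field: np.ndarray, target_shape) -> np.ndarray:
        if field.shape[:2] == tuple(target_shape):
            return field
        scale = np.array(target_shape, dtype=float) / np.array(
            field.shape[:2], dtype=float)
        return np.stack(
            [sktransform.resize(field[..., k], target_shape, order=1,
                                anti_aliasing=False) * scale[k]
             for k in range(2)], axis=-1)

    full_grid = grid
    u = np.zeros(pyramid_f[0].shape + (2,))
    metric_per_level = []
    for level, (f_lvl, m_lvl, n_iter) in enumerate(
            zip(pyramid_f, pyramid_m, cfg.iterations_per_level)):
        u = _upsample(u, f_lvl.shape)
        g = _sample_grid(f_lvl.shape)
        gr, gc = np.gradient(f_lvl)
        gmag2 = gr * gr + gc * gc
        for _ in range(n_iter):
            warped = _warp_image(m_lvl, g + u)
            diff = warped - f_lvl
            denom = gmag2 + diff * diff
            with np.errstate(divide="ignore", invalid="ignore"):
                step = np.where(denom > 1e-12, diff / denom, 0.0)
            u[..., 0] -= step * gr
            u[..., 1] -= step * gc
            u[..., 0] = ndimage.gaussian_filter(u[..., 0], cfg.smoothing_sigma_px)
            u[..., 1] = ndimage.gaussian_filter(u[..., 1], cfg.smoothing_sigma_px)
        # record the metric at full resolution so levels are comparable
        u_full = _upsample(u, shape)
        metric_per_level.append(mean_squares(
            fixed, _warp_image(moving_poly, full_grid + u_full)))

    u = _upsample(u, shape)

    # express the residual as a displacement added after the polynomial:
    # moving(poly(x + u(x))) == moving(poly(x) + disp(x))
    pts = (grid + u).reshape(-1, 2)
    disp = (init.map_points(pts).reshape(shape + (2,)) - poly_coords)
    ms_final = mean_squares(fixed, _warp_image(moving, poly_coords + disp))
    metadata = {"ms_init": ms_init, "ms_final": ms_final,
                "metric_per_level": metric_per_level}
    if not np.isfinite(ms_final) or ms_final > ms_init:
        warnings.warn("demons refinement could not improve the metric; "
                      "returning the polynomial-only warp", stacklevel=2)
        return WarpModel(init, np.zeros(shape + (2,)), shape,
                         {"ms_init": ms_init, "ms_final": ms_init,
                          "metric_per_level": metric_per_level,
                          "demons_rejected": True})
    return WarpModel(init, disp, shape, metadata)


def apply_warp_stack(stack: np.ndarray, w: WarpModel) -> np.ndarray:
    """Resample every channel of a moving-grid stack through the composed
    warp onto the fixed grid (bilinear; out-of-domain pixels 0).  The exact
    identity warp returns the stack unchanged."""
    stack = np.asarray(stack, dtype=float)
    single = stack.ndim == 2
    if single:
        stack = stack[None]
    if w.is_identity():
        out = stack.copy()
        return out[0] if single else out
    grid = _sample_grid(w.fixed_shape)
    coords = w.map_points(grid.reshape(-1, 2)).reshape(w.fixed_shape + (2,))
    out = np.stack([_warp_image(ch, coords) for ch in stack])
    return out[0] if single else out


def transfer_rois(rois: ROISet, w: WarpModel, target: str = "fixed",
                  moving_shape: tuple | None = None) -> ROISet:
    """Transfer fixed-grid ROI masks through the warp.

    ``target='fixed'`` is the identity overlay (the ISH stack is resampled
    onto the fixed grid).  ``target='moving'`` maps each mask to the moving
    grid with nearest-neighbor label resampling through the inverted warp;
    ROIs that land fully outside the target grid are dropped with a warning.
    """
    if target == "fixed":
        return ROISet([ROI(r.id, r.mask.copy()) for r in rois],
                      rois.image_shape)
    if target != "moving":
        raise ValueError("target must be 'fixed' or 'moving'")
    shape = tuple(moving_shape) if moving_shape is not None else w.fixed_shape
    grid = _sample_grid(shape).reshape(-1, 2)
    src = w.invert_points(grid).reshape(shape + (2,))
    out = []
    for r in rois:
        vals = ndimage.map_coordinates(
            r.mask.astype(np.uint8), [src[..., 0], src[..., 1]],
            order=0, mode="constant", cval=0)
        mask = vals.astype(bool)
        if not mask.any():
            warnings.warn(f"ROI {r.id!r} mapped fully outside the moving "
                          "grid; dropped", stacklevel=2)
            continue
        out.append(ROI(r.id, mask))
    return ROISet(out, shape)


def efficiency_specificity(label_calls, marker_calls=None) -> dict:
    """Labeling efficiency and marker specificity in percent.

    efficiency  = 100 * reporter-positive / all cells
    specificity = 100 * (reporter-positive AND marker-positive)
                        / reporter-positive   (None if no reporter+ cell)
    """
    label = np.asarray(label_calls, dtype=bool)
    n = label.size
    if n == 0:
        raise ValueError("no cells")
    n_label = int(label.sum())
    efficiency = 100.0 * n_label / n
    specificity = None
    if marker_calls is not None:
        marker = np.asarray(marker_calls, dtype=bool)
        if marker.shape != label.shape:
            raise ValueError("label and marker calls must align")
        if n_label > 0:
            specificity = 100.0 * int((label & marker).sum()) / n_label
    return {"efficiency": efficiency, "specificity": specificity}
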