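"""Inter-frame motion correction for fluorescence movie stacks.

Two-stage registration: a translation-only rough pass followed by a full
affine fine-tune.  Both stages minimize the mean-squares intensity metric
with a regular-step gradient-descent optimizer (step length halves whenever
the gradient direction reverses, iteration stops when the step falls below
``min_step``).

Coordinate convention: 0-based ``(row, col)``, pixel centers at integer
coordinates, transforms act about the image center.  A transform maps
*fixed*-grid coordinates into the *moving* image, i.e. the registered frame
is ``moving(T(x))`` sampled on the fixed grid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage


@dataclass
class AffineTransform2D:
    """2-D affine map ``y = A @ (x - c) + c + t`` in (row, col) pixels."""

    linear: np.ndarray = field(default_factory=lambda: np.eye(2))
    offset: np.ndarray = field(default_factory=lambda: np.zeros(2))
    center: np.ndarray = field(default_factory=lambda: np.zeros(2))
    converged: bool = True

    def __post_init__(self) -> None:
        self.linear = np.asarray(self.linear, dtype=float).reshape(2, 2)
        self.offset = np.asarray(self.offset, dtype=float).reshape(2)
        self.center = np.asarray(self.center, dtype=float).reshape(2)
        if not (np.isfinite(self.linear).all() and np.isfinite(self.offset).all()):
            raise ValueError("affine parameters must be finite")
        if abs(np.linalg.det(self.linear)) < 1e-12:
            raise ValueError("linear part of affine transform is singular")

    @classmethod
    def identity(cls, center=(0.0, 0.0)) -> "AffineTransform2D":
        return cls(np.eye(2), np.zeros(2), np.asarray(center, dtype=float))

    @classmethod
    def translation(cls, shift, center=(0.0, 0.0)) -> "AffineTransform2D":
        return cls(np.eye(2), np.asarray(shift, dtype=float), np.asarray(center, float))

    def is_identity(self, atol: float = 0.0) -> bool:
        return bool(
            np.allclose(self.linear, np.eye(2), atol=atol)
            and np.allclose(self.offset, 0.0, atol=atol)
        )

    def map_points(self, points: np.ndarray) -> np.ndarray:
        """Map an (N, 2) array of (row, col) points."""
        p = np.atleast_2d(np.asarray(points, dtype=float))
        return (p - self.center) @ self.linear.T + self.center + self.offset

    def inverse(self) -> "AffineTransform2D":
        inv = np.linalg.inv(self.linear)
        return AffineTransform2D(inv, -inv @ self.offset, self.center)

    def compose(self, other: "AffineTransform2D") -> "AffineTransform2D":
        """Return the transform equivalent to ``self`` applied after ``other``:
        ``result.map_points(x) == self.map_points(other.map_points(x))``."""
        a = self._as_matrix()
        b = other._as_matrix()
        m = a @ b
        return AffineTransform2D(m[:2, :2], m[:2, 2], center=(0.0, 0.0))

    def _as_matrix(self) -> np.ndarray:
        """3x3 homogeneous matrix with the center folded into the offset."""
        m = np.eye(3)
        m[:2, :2] = self.linear
        m[:2, 2] = self.center + self.offset - self.linear @ self.center
        return m

    def to_dict(self) -> dict:
        return {
            "linear": self.linear.tolist(),
            "offset": self.offset.tolist(),
            "center": self.center.tolist(),
            "converged": bool(self.converged),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AffineTransform2D":
        t = cls(np.array(d["linear"]), np.array(d["offset"]), np.array(d["center"]))
        t.converged = bool(d.get("converged", True))
        return t


@dataclass
class OptimizerConfig:
    initial_step: float = 2.0
    min_step: float = 0.01
    max_iterations: int = 200
    relaxation: float = 0.5

    def __post_init__(self) -> None:
        if not (0 < self.min_step <= self.initial_step):
            raise ValueError("require 0 < min_step <= initial_step")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if not (0 < self.relaxation < 1):
            raise ValueError("relaxation must lie in (0, 1)")


@dataclass
class MovieStack:
    """T x H x W fluorescence movie with acquisition metadata."""

    frames: np.ndarray
    frame_rate_hz: float = 5.0
    pixel_size_um: float = 1.0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[0] < 1:
            raise ValueError("frames must be a T x H x W array with T >= 1")
        if not np.isfinite(self.frames).all():
            raise ValueError("frames must be finite")
        if self.frame_rate_hz <= 0:
            raise ValueError("frame_rate_hz must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self):
        return self.frames.shape


def mean_squares(fixed: np.ndarray, moving: np.ndarray) -> float:
    """Mean of squared pixel differences over the common (finite) domain.

    NaN pixels in either image (used to mark out-of-domain samples) are
    excluded from the mean.
    """
    fixed = np.asarray(fixed, dtype=float)
    moving = np.asarray(moving, dtype=float)
    if fixed.shape != moving.shape:
        raise ValueError(f"shape mismatch: {fixed.shape} vs {moving.shape}")
    d = moving - fixed
    valid = np.isfinite(d)
    if not valid.any():
        return float("nan")
    return float(np.mean(d[valid] ** 2))


def apply_transform(image: np.ndarray, t: AffineTransform2D, *, order: int = 1,
                    cval: float = 0.0) -> np.ndarray:
    """Resample ``image`` through ``t`` onto its own grid.

    Bilinear interpolation by default (``order=0`` for label masks);
    out-of-domain pixels are set to ``cval``.  The exact identity transform
    returns the input unchanged.
    """
    image = np.asarray(image, dtype=float)
    if t.is_identity():
        return image.copy()
    h, w = image.shape
    rr, cc = np.meshgrid(np.arange(h, dtype=float), np.arange(w, dtype=float),
                         indexing="ij")
    pts = t.map_points(np.column_stack([rr.ravel(), cc.ravel()]))
    coords = pts.T.reshape(2, h, w)
    return ndimage.map_coordinates(image, coords, order=order, cval=cval,
                                   mode="constant")


def _sample(image: np.ndarray, coords: np.ndarray) -> np.ndarray:
    """Bilinear sample with NaN outside the grid (coords: 2 x N)."""
    return ndimage.map_coordinates(image, coords, order=1, mode="constant",
                                   cval=np.nan)


class _AffineMetric:
    """Mean-squares metric of moving(T(x)) vs fixed, with analytic gradient.

    Parameters are expressed in a normalized space where a unit step in any
    coordinate moves image content by roughly one pixel: offsets are in
    pixels and matrix perturbations are divided by half the larger image
    dimension.
    """

    def __init__(self, fixed: np.ndarray, moving: np.ndarray,
                 center: np.ndarray, translation_only: bool):
        self.fixed = np.asarray(fixed, dtype=float)
        self.moving = np.asarray(moving, dtype=float)
        if self.fixed.shape != self.moving.shape:
            raise ValueError("fixed and moving must share a shape")
        self.center = np.asarray(center, dtype=float)
        self.translation_only = translation_only
        h, w = self.fixed.shape
        self.halfdim = max(h, w) / 2.0
        rr, cc = np.meshgrid(np.arange(h, dtype=float),
                             np.arange(w, dtype=float), indexing="ij")
        self.grid = np.column_stack([rr.ravel(), cc.ravel()])  # N x 2
        self.fvals = self.fixed.ravel()
        gr, gc = np.gradient(self.moving)
        self.mov_grad = (gr, gc)

    @property
    def n_params(self) -> int:
        return 2 if self.translation_only else 6

    def params_from_transform(self, t: AffineTransform2D) -> np.ndarray:
        if self.translation_only:
            return t.offset.copy()
        dm = (t.linear - np.eye(2)).ravel() * self.halfdim
        return np.concatenate([dm, t.offset])

    def transform_from_params(self, p: np.ndarray) -> AffineTransform2D:
        if self.translation_only:
            return AffineTransform2D(np.eye(2), p.copy(), self.center)
        linear = np.eye(2) + p[:4].reshape(2, 2) / self.halfdim
        return AffineTransform2D(linear, p[4:6].copy(), self.center)

    def value_and_gradient(self, p: np.ndarray):
        t = self.transform_from_params(p)
        pts = t.map_points(self.grid)  # N x 2 sample positions in moving
        coords = pts.T
        w = _sample(self.moving, coords)
        valid = np.isfinite(w)
        n = int(valid.sum())
        if n == 0:
            return float("nan"), np.zeros(self.n_params)
        diff = np.where(valid, w - self.fvals, 0.0)
        value = float(np.sum(diff**2) / n)
        gr = np.where(valid, _sample(self.mov_grad[0], coords), 0.0)
        gc = np.where(valid, _sample(self.mov_grad[1], coords), 0.0)
        wdiff = 2.0 * diff / n
        g_off = np.array([np.sum(wdiff * gr), np.sum(wdiff * gc)])
        if self.translation_only:
            return value, g_off
        rel = self.grid - self.center  # N x 2
        g_mat = np.array([
            np.sum(wdiff * gr * rel[:, 0]),
            np.sum(wdiff * gr * rel[:, 1]),
            np.sum(wdiff * gc * rel[:, 0]),
            np.sum(wdiff * gc * rel[:, 1]),
        ]) / self.halfdim
        return value, np.concatenate([g_mat, g_off])


def _regular_step_descent(metric: _AffineMetric, p0: np.ndarray,
                          opt: OptimizerConfig):
    """Regular-step gradient descent; returns (best_params, best_value,
    initial_value, converged)."""
    p = np.asarray(p0, dtype=float).copy()
    value, grad = metric.value_and_gradient(p)
    init_value = value
    best_p, best_v = p.copy(), value
    gnorm = float(np.linalg.norm(grad))
    if not np.isfinite(value):
        return best_p, best_v, init_value, False
    if gnorm < 1e-30:  # already stationary (e.g. identical images)
        return best_p, best_v, init_value, True
    step = opt.initial_step
    direction = -grad / gnorm
    converged = False
    for _ in range(opt.max_iterations):
        p = p + step * direction
        value, grad = metric.value_and_gradient(p)
        if np.isfinite(value) and value < best_v:
            best_v, best_p = value, p.copy()
        gnorm = float(np.linalg.norm(grad))
        if not np.isfinite(value) or gnorm < 1e-30:
            converged = True
            break
        new_direction = -grad / gnorm
        if float(np.dot(new_direction, direction)) < 0.0:
            step *= opt.relaxation
        direction = new_direction
        if step < opt.min_step:
            converged = True
            break
    return best_p, best_v, init_value, converged


DEFAULT_TRANSLATION_OPT = OptimizerConfig(initial_step=2.0, min_step=0.01,
                                          max_iterations=200, relaxation=0.5)
DEFAULT_AFFINE_OPT = OptimizerConfig(initial_step=0.5, min_step=0.01,
                                     max_iterations=200, relaxation=0.5)


def _image_center(image: np.ndarray) -> np.ndarray:
    h, w = image.shape
    return np.array([(h - 1) / 2.0, (w - 1) / 2.0])


def estimate_translation(fixed: np.ndarray, moving: np.ndarray,
                         opt: OptimizerConfig | None = None) -> AffineTransform2D:
    """Translation-only registration (rough pass).

    Returns the translation minimizing the mean-squares metric; on a
    constant image (zero gradient) the identity is returned with
    ``converged=False`` and a warning.
    """
    opt = opt or DEFAULT_TRANSLATION_OPT
    center = _image_center(np.asarray(fixed))
    if np.ptp(moving) == 0 or np.ptp(fixed) == 0:
        warnings.warn("constant image: translation registration cannot "
                      "converge", stacklevel=2)
        t = AffineTransform2D.identity(center)
        t.converged = False
        return t
    metric = _AffineMetric(fixed, moving, center, translation_only=True)
    p, _, _, converged = _regular_step_descent(metric, np.zeros(2), opt)
    if not converged:
        warnings.warn("translation registration did not converge", stacklevel=2)
    t = metric.transform_from_params(p)
    t.converged = converged
    return t


def refine_affine(fixed: np.ndarray, moving: np.ndarray,
                  init: AffineTransform2D,
                  opt: OptimizerConfig | None = None) -> AffineTransform2D:
    """Full-affine fine-tune initialized at ``init``.

    Guaranteed not to worsen the metric relative to ``init`` (the best
    visited parameter vector is returned).
    """
    opt = opt or DEFAULT_AFFINE_OPT
    center = _image_center(np.asarray(fixed))
    if np.ptp(moving) == 0 or np.ptp(fixed) == 0:
        warnings.warn("constant image: affine registration cannot converge",
                      stacklevel=2)
        t = AffineTransform2D.identity(center)
        t.converged = False
        return t
    if not np.allclose(init.center, center):
        # re-center: fold the old center into an equivalent offset
        m = init._as_matrix()
        linear = m[:2, :2]
        offset = m[:2, 2] + linear @ center - center
        init = AffineTransform2D(linear, offset, center)
    metric = _AffineMetric(fixed, moving, center, translation_only=False)
    p0 = metric.params_from_transform(init)
    p, _, _, converged = _regular_step_descent(metric, p0, opt)
    if not converged:
        warnings.warn("affine registration did not converge", stacklevel=2)
    t = metric.transform_from_params(p)
    t.converged = converged
    return t


def register_stack(movie: MovieStack, opt: OptimizerConfig | None = None,
                   reference: str = "mean_image",
                   affine_opt: OptimizerConfig | None = None):
    """Register every frame of a movie to a reference image.

    Each frame is registered by :func:`estimate_translation` followed by
    :func:`refine_affine`.  Returns ``(registered_movie, transforms)``.
    Per-frame non-convergence is reported as a warning carrying the frame
    index; the stack is never aborted.
    """
    if movie.n_frames < 2:
        raise ValueError("need at least 2 frames to register a stack")
    if reference == "mean_image":
        ref = movie.frames.mean(axis=0)
    elif reference == "first_frame":
        ref = movie.frames[0]
    else:
        raise ValueError("reference must be 'mean_image' or 'first_frame'")
    transforms: list[AffineTransform2D] = []
    out = np.empty_like(movie.frames)
    for i in range(movie.n_frames):
        frame = movie.frames[i]
        pre = mean_squares(ref, frame)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            t = estimate_translation(ref, frame, opt)
            t = refine_affine(ref, frame, t, affine_opt)
        # metric-monotone guarantee (evaluated over the overlap domain):
        # fall back to identity if the frame could not be improved
        reg_nan = apply_transform(frame, t, cval=np.nan)
        post = mean_squares(ref, reg_nan)
        if not np.isfinite(post) or post > pre:
            t = AffineTransform2D.identity(_image_center(ref))
            t.converged = False
            reg = frame.copy()
        else:
            # fill out-of-overlap pixels from the reference so border strips
            # do not bias downstream ROI/neuropil means
            reg = np.where(np.isfinite(reg_nan), reg_nan, ref)
        if not t.converged:
            warnings.warn(f"frame {i}: registration did not converge",
                          stacklevel=2)
        transforms.append(t)
        out[i] = reg
    return MovieStack(out, movie.frame_rate_hz, movie.pixel_size_um), transforms
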