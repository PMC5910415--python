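"""Frame preprocessing: illumination correction, background subtraction, denoising.

Two illumination corrections are provided: normalisation by a pre-bleach
mean image, and flattening with a mask derived from imaging a homogeneously
distributed fluorophore. Both add an offset (max of the two data minima,
plus one) before dividing so that noise-induced near-zero denominators
cannot blow up. Corrections operate on raw intensities; denoising, when
enabled, is applied last.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage

from .rois import ImageStack

__all__ = [
    "CorrectionMask",
    "mean_image",
    "compute_offset",
    "normalize_by_prebleach",
    "flatten",
    "subtract_background",
    "denoise",
    "denoise_stack",
    "SIGMA_GAUSS_DEFAULT",
    "R_MEDIAN_DEFAULT",
]

#: default Gaussian-blur standard deviation (pixels)
SIGMA_GAUSS_DEFAULT = 2.0
#: default median-filter window radius (pixels)
R_MEDIAN_DEFAULT = 5


@dataclass
class CorrectionMask:
    kind: str  # prebleach_mean | flatfield | background
    values: np.ndarray
    offset: float = 0.0


def mean_image(frames: Sequence[np.ndarray] | np.ndarray) -> np.ndarray:
    """Pixel-wise arithmetic mean over a list of equally shaped frames."""
    frames = np.asarray(frames, dtype=float)
    if frames.ndim == 2:
        frames = frames[None]
    if frames.shape[0] == 0:
        raise ValueError("need at least one frame")
    return frames.mean(axis=0)


def compute_offset(stack_min: float, mask_min: float) -> float:
    """Data offset guarding against division by ~0: max of the two global
    minima, plus one."""
    return float(max(stack_min, mask_min)) + 1.0


def normalize_by_prebleach(stack: ImageStack, prebleach_frames) -> ImageStack:
    """Divide each frame pixel-wise by the pre-bleach mean image, offsetting
    numerator and denominator alike. The result is dimensionless and ≈1
    where recovery intensity matches the pre-bleach level."""
    m_pre = mean_image(prebleach_frames)
    if m_pre.shape != stack.shape:
        raise ValueError("pre-bleach mask shape does not match frames")
    offset = compute_offset(stack.frames.min(), m_pre.min())
    frames = (stack.frames + offset) / (m_pre + offset)
    return ImageStack(frames, stack.times.copy(), stack.frame_interval)


def flatten(stack: ImageStack, flat_frames) -> ImageStack:
    """Multiply each frame by the flattening mask
    ``F = (max(M_flat) + O) / (M_flat + O)`` so that a frame proportional to
    the flat-field image becomes spatially uniform."""
    m_flat = mean_image(flat_frames)
    if m_flat.shape != stack.shape:
        raise ValueError("flat-field mask shape does not match frames")
    offset = compute_offset(stack.frames.min(), m_flat.min())
    f = (m_flat.max() + offset) / (m_flat + offset)
    return ImageStack(f * stack.frames, stack.times.copy(), stack.frame_interval)


def subtract_background(stack: ImageStack, bkgd_frames) -> ImageStack:
    """Subtract the mean background image pixel-wise (no clipping)."""
    m_bkgd = mean_image(bkgd_frames)
    if m_bkgd.shape != stack.shape:
        raise ValueError("background mask shape does not match frames")
    return ImageStack(stack.frames - m_bkgd, stack.times.copy(), stack.frame_interval)


def _disc_footprint(radius: int) -> np.ndarray:
    r = int(radius)
    y, x = np.mgrid[-r : r + 1, -r : r + 1]
    return x * x + y * y <= r * r


def denoise(frame: np.ndarray, method: str = "gaussian", param: float | None = None) -> np.ndarray:
    """Smooth a frame with a Gaussian blur (reflect padding) or a median
    filter with a disc-shaped window."""
    frame = np.asarray(frame, dtype=float)
    if method == "gaussian":
        sigma = SIGMA_GAUSS_DEFAULT if param is None else float(param)
        if sigma <= 0:
            raise ValueError("sigma must be positive")
        return ndimage.gaussian_filter(frame, sigma=sigma, mode="reflect")
    if method == "median":
        radius = R_MEDIAN_DEFAULT if param is None else int(param)
        if radius <= 0:
            raise ValueError("radius must be positive")
        return ndimage.median_filter(frame, footprint=_disc_footprint(radius), mode="reflect")
    raise ValueError(f"unknown denoising method {method!r}")


def denoise_stack(stack: ImageStack, method: str = "gaussian", param: float | None = None) -> ImageStack:
    frames = np.stack([denoise(f, method=method, param=param) for f in stack.frames])
    return ImageStack(frames, stack.times.copy(), stack.frame_interval)
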