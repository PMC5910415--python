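"""Regions of interest and recovery-curve extraction.

A FRAP data set is a time series of single-channel frames. Analysis reduces
each frame to mean intensities over named regions of interest (ROIs): the
bleached region, the circular imaging ("slice") region, and a rim annulus
used to estimate the fluorophore concentration outside the field of view.

Conventions
-----------
* Images are ``(n_t, n_y, n_x)`` arrays indexed ``[frame, row, col]``.
* A pixel is the point at its integer centre: pixel ``(row=i, col=j)`` sits
  at ``(x=j, y=i)``, 0-based. Membership tests evaluate the pixel centre;
  there is no partial-pixel weighting.
* Circle membership is strict (``distance < radius``); boundary ties are
  excluded.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "ROI",
    "CircleROI",
    "SquareROI",
    "AnnulusROI",
    "DifferenceROI",
    "ImageStack",
    "RecoveryCurve",
    "RecoveryCurveSet",
    "roi_pixels",
    "roi_mask",
    "roi_mean_intensity",
    "extract_curves",
    "make_standard_rois",
    "estimate_rim_concentration",
]


class ROI:
    """Base class for named spatial regions with decidable membership."""

    name: str
    #: depth interval (z_lo, z_hi) used when integrating 3D simulations;
    #: ignored for 2D analysis.
    z_extent: tuple[float, float] | None

    def contains(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Vectorised membership test for continuous coordinates."""
        raise NotImplementedError

    def with_z_extent(self, z_lo: float, z_hi: float) -> "ROI":
        return replace(self, z_extent=(float(z_lo), float(z_hi)))


@dataclass(frozen=True)
class CircleROI(ROI):
    name: str
    center: tuple[float, float]
    radius: float
    z_extent: tuple[float, float] | None = None

    def contains(self, x, y):
        dx = np.asarray(x, dtype=float) - self.center[0]
        dy = np.asarray(y, dtype=float) - self.center[1]
        return dx * dx + dy * dy < self.radius**2


@dataclass(frozen=True)
class SquareROI(ROI):
    """Axis-aligned square; ``corner`` is the lower-left (min-x, min-y) corner."""

    name: str
    corner: tuple[float, float]
    side: float
    z_extent: tuple[float, float] | None = None

    def contains(self, x, y):
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        x0, y0 = self.corner
        return (x >= x0) & (x < x0 + self.side) & (y >= y0) & (y < y0 + self.side)


@dataclass(frozen=True)
class AnnulusROI(ROI):
    name: str
    center: tuple[float, float]
    r_in: float
    r_out: float
    z_extent: tuple[float, float] | None = None

    def contains(self, x, y):
        dx = np.asarray(x, dtype=float) - self.center[0]
        dy = np.asarray(y, dtype=float) - self.center[1]
        d2 = dx * dx + dy * dy
        return (d2 >= self.r_in**2) & (d2 < self.r_out**2)


@dataclass(frozen=True)
class DifferenceROI(ROI):
    """Set difference ``a − b``: pixels of ``a`` that are not in ``b``."""

    name: str
    a: ROI
    b: ROI
    z_extent: tuple[float, float] | None = None

    def contains(self, x, y):
        return self.a.contains(x, y) & ~self.b.contains(x, y)


@dataclass
class ImageStack:
    """Ordered single-channel frames with acquisition times.

    ``times[0] == 0`` by convention: the first post-bleach frame defines the
    experiment's time origin.
    """

    frames: np.ndarray  # (n_t, n_y, n_x)
    times: np.ndarray  # seconds, strictly increasing
    frame_interval: float  # seconds

    def __post_init__(self):
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (n_t, n_y, n_x) array")
        self.times = np.asarray(self.times, dtype=float)
        if len(self.times) != self.frames.shape[0]:
            raise ValueError("times and frames disagree in length")
        if len(self.times) and np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]

    @classmethod
    def from_tiff(cls, path, frame_interval: float) -> "ImageStack":
        """Read a multi-page grayscale TIFF; frame order = page order,
        times = page index × frame_interval."""
        frames = tifffile.imread(path)
        frames = np.atleast_3d(frames)
        if frames.ndim == 2:
            frames = frames[None]
        frames = np.asarray(frames, dtype=float)
        times = np.arange(frames.shape[0]) * float(frame_interval)
        return cls(frames=frames, times=times, frame_interval=float(frame_interval))

    def to_tiff(self, path) -> None:
        tifffile.imwrite(
            path, np.asarray(self.frames, dtype=np.float32), photometric="minisblack"
        )


@dataclass
class RecoveryCurve:
    roi_name: str
    times: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if len(self.times) != len(self.values):
            raise ValueError("times and values disagree in length")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("recovery-curve values must be finite")


class RecoveryCurveSet(Mapping):
    """Recovery curves keyed by ROI name, all on a common time grid."""

    def __init__(self, curves: Sequence[RecoveryCurve]):
        self._curves = {c.roi_name: c for c in curves}
        times = [c.times for c in curves]
        for t in times[1:]:
            if len(t) != len(times[0]) or not np.allclose(t, times[0]):
                raise ValueError("all curves must share one time grid")
        self.times = times[0] if times else np.empty(0)

    def __getitem__(self, key):
        return self._curves[key]

    def __iter__(self):
        return iter(self._curves)

    def __len__(self):
        return len(self._curves)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"roi": name, "time_s": t, "mean_intensity": v}
            for name, c in self._curves.items()
            for t, v in zip(c.times, c.values)
        ]
        return pd.DataFrame(rows, columns=["roi", "time_s", "mean_intensity"])

    def to_csv(self, path_or_buf) -> None:
        self.to_frame().to_csv(path_or_buf, index=False)

    @classmethod
    def from_csv(cls, path_or_buf) -> "RecoveryCurveSet":
        df = pd.read_csv(path_or_buf)
        curves = [
            RecoveryCurve(str(name), g["time_s"].to_numpy(), g["mean_intensity"].to_numpy())
            for name, g in df.groupby("roi", sort=False)
        ]
        return cls(curves)


def _pixel_grid(image_shape: tuple[int, int]):
    n_y, n_x = image_shape
    y, x = np.mgrid[0:n_y, 0:n_x]
    return x, y


def roi_mask(roi: ROI, image_shape: tuple[int, int]) -> np.ndarray:
    """Boolean membership mask of shape ``image_shape``."""
    n_y, n_x = image_shape
    if n_y <= 0 or n_x <= 0:
        raise ValueError("image_shape must be positive")
    x, y = _pixel_grid(image_shape)
    return roi.contains(x, y)


def roi_pixels(roi: ROI, image_shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
    """Pixel coordinates ``(rows, cols)`` of all member pixel centres.

    Warns (and returns empty arrays) if the ROI contains no pixel of the
    image, e.g. because it lies entirely outside the frame.
    """
    mask = roi_mask(roi, image_shape)
    rows, cols = np.nonzero(mask)
    if rows.size == 0:
        warnings.warn(
            f"ROI {roi.name!r} contains no pixel of a {image_shape} image",
            stacklevel=2,
        )
    return rows, cols


def roi_mean_intensity(stack: ImageStack, roi: ROI) -> RecoveryCurve:
    """Mean intensity over the ROI per frame (discrete pixel-centre sum
    divided by the member-pixel count)."""
    mask = roi_mask(roi, stack.shape)
    n_pix = int(mask.sum())
    if n_pix == 0:
        raise ValueError(f"empty ROI {roi.name!r}")
    values = stack.frames[:, mask].mean(axis=1)
    return RecoveryCurve(roi.name, stack.times.copy(), values)


def extract_curves(stack: ImageStack, rois: Sequence[ROI] | Mapping[str, ROI]) -> RecoveryCurveSet:
    if isinstance(rois, Mapping):
        rois = list(rois.values())
    return RecoveryCurveSet([roi_mean_intensity(stack, r) for r in rois])


def make_standard_rois(
    center: tuple[float, float],
    r_slice: float,
    s_bleached: float,
    rho_rim: float = 0.66,
) -> dict[str, ROI]:
    """Standard FRAP ROI triple.

    * ``slice``: circle of radius ``r_slice`` around ``center`` (the confocal
      imaging region used for normalisation and fitting),
    * ``bleached``: square of side ``s_bleached`` with lower-left corner at
      ``center − ½(s, s)``,
    * ``rim``: annulus ``slice − circle(center, rho_rim · r_slice)`` from
      whose first post-bleach frame the out-of-view concentration is
      estimated.

    ``rho_rim`` defaults to 0.66 (the in vitro value; 0.4585 suits dome-stage
    embryo data).
    """
    if not 0 < rho_rim < 1:
        raise ValueError("rho_rim must lie in (0, 1)")
    if r_slice <= 0:
        raise ValueError("r_slice must be positive")
    if s_bleached > 2 * r_slice:
        warnings.warn("bleached square exceeds the slice circle", stacklevel=2)
    cx, cy = center
    slice_roi = CircleROI("slice", (cx, cy), r_slice)
    bleached = SquareROI("bleached", (cx - s_bleached / 2, cy - s_bleached / 2), s_bleached)
    center_roi = CircleROI("center", (cx, cy), rho_rim * r_slice)
    rim = DifferenceROI("rim", slice_roi, center_roi)
    return {"slice": slice_roi, "bleached": bleached, "rim": rim}


def estimate_rim_concentration(first_frame: np.ndarray, rim: ROI) -> float:
    """Mean intensity of the first post-bleach frame over the rim ROI: the
    proxy concentration assigned to sample regions outside the image."""
    first_frame = np.asarray(first_frame, dtype=float)
    mask = roi_mask(rim, first_frame.shape)
    if not mask.any():
        raise ValueError("empty rim ROI")
    return float(first_frame[mask].mean())
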