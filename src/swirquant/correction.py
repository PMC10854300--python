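"""Frame-correction pipeline: dark-noise subtraction, outlier removal,
cropping and exposure normalization.

The outlier rule is a robust despeckle: a pixel deviating from the median of
its (2r+1)^2 neighborhood (center excluded) by more than k times that
neighborhood's median absolute deviation (MAD) is replaced by the median;
everything else is left untouched.  Defaults r=2, k=10 remove saturated hot pixels while leaving
photon noise alone.  All rectangles are half-open, 0-based, row-major.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Union

import numpy as np
from scipy import ndimage

from .stack import ImageStack

__all__ = ["CorrectionConfig", "subtract_dark", "remove_outliers", "crop",
           "normalize_exposure", "correct_stack"]


@dataclass(frozen=True)
class CorrectionConfig:
    """Parameters of the correction pipeline.

    ``dark_value`` is a scalar dark-count level or a reference dark frame;
    ``crop_window`` is ``(r0, r1, c0, c1)`` half-open, or ``None`` to skip.
    """

    dark_value: Union[float, np.ndarray] = 0.0
    outlier_radius: int = 2
    outlier_k: float = 10.0
    crop_window: tuple[int, int, int, int] | None = None

    def __post_init__(self) -> None:
        if self.outlier_radius < 1:
            raise ValueError("outlier_radius must be >= 1")
        if not self.outlier_k > 0:
            raise ValueError("outlier_k must be > 0")


def subtract_dark(stack: ImageStack, dark: Union[float, np.ndarray]) -> ImageStack:
    """Subtract a dark level (scalar or per-pixel frame), flooring at zero.

    The number of floored pixels is recorded in ``meta['dark_floored_pixels']``
    since flooring discards information the dB math downstream cannot use.
    """
    dark_arr = np.asarray(dark, dtype=np.float64)
    if not np.all(np.isfinite(dark_arr)):
        raise ValueError("dark reference must be finite")
    if dark_arr.ndim == 2 and dark_arr.shape != stack.frame_shape:
        raise ValueError(
            f"dark frame shape {dark_arr.shape} != frame shape {stack.frame_shape}")
    if dark_arr.ndim not in (0, 2):
        raise ValueError("dark must be a scalar or a single 2-D frame")
    diff = stack.frames - dark_arr
    floored = int(np.count_nonzero(diff < 0))
    return stack.with_frames(np.maximum(diff, 0.0),
                             dark_subtracted=float(dark_arr.mean()),
                             dark_floored_pixels=floored)


def _despeckle_frame(frame: np.ndarray, radius: int, k: float) -> tuple[np.ndarray, int]:
    # The center pixel is excluded from its own neighborhood: with it
    # included, the window median on a steep intensity ramp is frequently the
    # center sample itself, collapsing the local MAD to zero and flagging
    # ordinary gradient pixels as outliers.
    size = 2 * radius + 1
    footprint = np.ones((size, size), dtype=bool)
    footprint[radius, radius] = False
    med = ndimage.median_filter(frame, footprint=footprint, mode="reflect")
    mad = ndimage.median_filter(np.abs(frame - med), footprint=footprint,
                                mode="reflect")
    outliers = np.abs(frame - med) > k * mad
    out = frame.copy()
    out[outliers] = med[outliers]
    return out, int(outliers.sum())


def remove_outliers(stack: ImageStack, cfg: CorrectionConfig = CorrectionConfig()) -> ImageStack:
    """Replace median/MAD outliers by the local median, frame by frame.

    Only pixels exceeding the deviation rule are modified.  Where the local
    MAD is zero (flat neighborhood) any deviation from the median counts as
    an outlier, which is what removes isolated saturated pixels.
    """
    rows, cols = stack.frame_shape
    if 2 * cfg.outlier_radius + 1 > min(rows, cols):
        raise ValueError(
            f"outlier_radius {cfg.outlier_radius} too large for frame {stack.frame_shape}")
    corrected = np.empty_like(stack.frames)
    n_replaced = 0
    for i, frame in enumerate(stack.frames):
        corrected[i], n = _despeckle_frame(frame, cfg.outlier_radius, cfg.outlier_k)
        n_replaced += n
    return stack.with_frames(corrected,
                             outlier_radius=cfg.outlier_radius,
                             outlier_k=cfg.outlier_k,
                             outliers_replaced=n_replaced)


def crop(stack: ImageStack, window: tuple[int, int, int, int]) -> ImageStack:
    """Crop every frame to the half-open window ``(r0, r1, c0, c1)``."""
    r0, r1, c0, c1 = window
    rows, cols = stack.frame_shape
    if not (0 <= r0 < r1 <= rows and 0 <= c0 < c1 <= cols):
        raise ValueError(f"crop window {window} invalid for frame {stack.frame_shape}")
    return stack.with_frames(stack.frames[:, r0:r1, c0:c1],
                             crop_window=[r0, r1, c0, c1])


def normalize_exposure(stack: ImageStack) -> ImageStack:
    """Divide intensities by the exposure time; unit becomes counts/ms."""
    if stack.unit == "counts_per_ms":
        raise ValueError("stack is already exposure-normalized")
    normalized = stack.with_frames(stack.frames / stack.exposure_ms,
                                   normalized_from_exposure_ms=stack.exposure_ms)
    return ImageStack(normalized.frames, exposure_ms=stack.exposure_ms,
                      cutoff_nm=stack.cutoff_nm, unit="counts_per_ms",
                      meta=normalized.meta)


def correct_stack(stack: ImageStack, cfg: CorrectionConfig,
                  normalize: bool = False) -> ImageStack:
    """Full pipeline: dark subtraction, despeckle, optional crop, optional
    exposure normalization — in the acquisition-software order."""
    out = subtract_dark(stack, cfg.dark_value)
    out = remove_outliers(out, cfg)
    if cfg.crop_window is not None:
        out = crop(out, cfg.crop_window)
    if normalize:
        out = normalize_exposure(out)
    return out
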