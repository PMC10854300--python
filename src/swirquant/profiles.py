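"""Line profiles through a frame and FWHM quantification.

Used to compare tumor-core sharpness between long-pass cutoffs: a narrower
full width at half maximum along a line through the tumor indicates better
core delineation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

__all__ = ["LineProfile", "FWHMResult", "line_profile", "fwhm"]


@dataclass(frozen=True)
class LineProfile:
    """Intensities along one row or column of a frame.

    ``baseline`` is the background level used for the half-max computation;
    by default the profile's 10th percentile.
    """

    axis: str                     # "horizontal" (a row) or "vertical" (a column)
    fixed_coordinate: int
    samples: np.ndarray
    baseline: float

    def __post_init__(self) -> None:
        if self.axis not in ("horizontal", "vertical"):
            raise ValueError("axis must be 'horizontal' or 'vertical'")
        if self.baseline < 0:
            raise ValueError("baseline must be >= 0")
        object.__setattr__(self, "samples",
                           np.asarray(self.samples, dtype=np.float64))


@dataclass(frozen=True)
class FWHMResult:
    width_px: float
    left_px: float
    right_px: float
    half_level: float
    ambiguous: bool = False       # multiple crossings; outermost used


def line_profile(frame: np.ndarray, axis: str, fixed_coordinate: int,
                 baseline_percentile: float = 10.0,
                 smooth_width: int = 1) -> LineProfile:
    """Extract a horizontal (row) or vertical (column) intensity profile.

    ``smooth_width`` applies an odd moving-average window before returning
    (1 = no smoothing).
    """
    frame = np.asarray(frame, dtype=np.float64)
    if frame.ndim != 2:
        raise ValueError("frame must be 2-D")
    rows, cols = frame.shape
    if axis == "horizontal":
        if not 0 <= fixed_coordinate < rows:
            raise IndexError(f"row {fixed_coordinate} out of bounds for {rows} rows")
        samples = frame[fixed_coordinate, :]
    elif axis == "vertical":
        if not 0 <= fixed_coordinate < cols:
            raise IndexError(f"column {fixed_coordinate} out of bounds for {cols} columns")
        samples = frame[:, fixed_coordinate]
    else:
        raise ValueError("axis must be 'horizontal' or 'vertical'")
    if smooth_width > 1:
        if smooth_width % 2 == 0:
            raise ValueError("smooth_width must be odd")
        half = smooth_width // 2
        padded = np.pad(samples, half, mode="edge")
        samples = np.convolve(padded, np.ones(smooth_width) / smooth_width,
                              mode="valid")
    baseline = float(np.percentile(samples, baseline_percentile))
    return LineProfile(axis=axis, fixed_coordinate=fixed_coordinate,
                       samples=samples, baseline=max(baseline, 0.0))


def _crossings(samples: np.ndarray, level: float) -> np.ndarray:
    """Sub-pixel positions where the profile crosses ``level``, by linear
    interpolation between adjacent samples."""
    above = samples >= level
    idx = np.flatnonzero(above[:-1] != above[1:])
    y0, y1 = samples[idx], samples[idx + 1]
    return idx + (level - y0) / (y1 - y0)


def fwhm(profile: LineProfile, baseline: Optional[float] = None) -> FWHMResult:
    """Full width at half maximum of a line profile, in pixels.

    The half-max level is ``baseline + (max - baseline) / 2``; the two
    crossings bracketing the peak are located by linear interpolation.  When
    more than one crossing exists on a side (multimodal profile) the
    outermost pair is used and the result is flagged ambiguous.  A peak
    whose half-max level is never crossed on one side (peak at the edge)
    is an error.
    """
    samples = profile.samples
    base = profile.baseline if baseline is None else baseline
    peak_idx = int(np.argmax(samples))
    peak = samples[peak_idx]
    if peak <= base:
        raise ValueError("profile maximum does not exceed the baseline")
    level = base + 0.5 * (peak - base)
    crossings = _crossings(samples, level)
    left = crossings[crossings <= peak_idx]
    right = crossings[crossings >= peak_idx]
    if left.size == 0 or right.size == 0:
        raise ValueError("half-max level not crossed on both sides of the peak")
    ambiguous = left.size > 1 or right.size > 1
    left_px, right_px = float(left[0]), float(right[-1])
    return FWHMResult(width_px=right_px - left_px, left_px=left_px,
                      right_px=right_px, half_level=float(level),
                      ambiguous=ambiguous)
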