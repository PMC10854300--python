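"""Pixelwise "contrast mode": per-frame CNR maps in dB and binary delineation.

Given a user-chosen non-tumor background reference ROI, each frame is
transformed pixel by pixel as

    PixelNew = 10 * log10((PixelOld - ROIAvg) / ROIStd)

where ROIAvg/ROIStd are the sample mean and SD of the background ROI,
recomputed per frame ("framewise").  Pixels at or below the background mean
have no defined dB value and are excluded via a validity mask rather than
clamped: only positive contrast matters for delineation.  The binary tumor
mask is valid AND dB > threshold, with the Rose criterion's 3 dB default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .roi import CNR_THRESHOLD_DB, ROI, ROIStats, roi_stats
from .stack import ImageStack

__all__ = ["ContrastImage", "DelineationSummary", "contrast_transform",
           "binary_delineation"]


@dataclass(frozen=True)
class ContrastImage:
    """Per-pixel CNR map of one frame.

    ``db`` is NaN outside ``valid`` (pixels not above the background mean);
    ``above_threshold`` is ``valid & (db > threshold_db)``.
    """

    db: np.ndarray
    valid: np.ndarray
    above_threshold: np.ndarray
    threshold_db: float
    background: ROIStats
    frame_index: int = 0

    def __post_init__(self) -> None:
        if np.any(self.above_threshold & ~self.valid):
            raise AssertionError("threshold mask must be a subset of validity mask")

    def rethreshold(self, threshold_db: float) -> "ContrastImage":
        """Same dB map with a different delineation threshold."""
        mask = self.valid & (self.db > threshold_db)
        return ContrastImage(self.db, self.valid, mask, threshold_db,
                             self.background, self.frame_index)


@dataclass(frozen=True)
class DelineationSummary:
    """Binary delineation mask with its area."""

    mask: np.ndarray
    area_px: int
    fraction_of_frame: float


def contrast_transform(stack: ImageStack, background_roi: ROI,
                       threshold_db: float = CNR_THRESHOLD_DB,
                       fixed_stats: ROIStats | None = None) -> list[ContrastImage]:
    """Apply the contrast-mode transform to every frame of a stack.

    Background statistics are recomputed from ``background_roi`` on each
    frame; pass ``fixed_stats`` to reuse one (mean, SD) pair for all frames
    (streaming use).  A frame whose background ROI has zero SD is an error
    naming the frame.
    """
    images: list[ContrastImage] = []
    for i in range(stack.n_frames):
        if fixed_stats is not None:
            bg = fixed_stats
        else:
            bg = roi_stats(stack, background_roi, frame_index=i)
        if not bg.sd > 0:
            raise ValueError(f"background ROI has zero SD in frame {i}")
        frame = stack.frame(i)
        diff = frame - bg.mean
        valid = diff > 0
        db = np.full(frame.shape, np.nan)
        db[valid] = 10.0 * np.log10(diff[valid] / bg.sd)
        mask = valid & (db > threshold_db)
        images.append(ContrastImage(db=db, valid=valid, above_threshold=mask,
                                    threshold_db=threshold_db, background=bg,
                                    frame_index=i))
    return images


def binary_delineation(contrast: ContrastImage) -> DelineationSummary:
    """The supra-threshold mask of a contrast image and its pixel count."""
    mask = contrast.above_threshold
    area = int(mask.sum())
    return DelineationSummary(mask=mask, area_px=area,
                              fraction_of_frame=area / mask.size)
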