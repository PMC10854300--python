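"""Image-stack container shared by every pipeline stage.

A stack is an ordered sequence of 2-D grayscale frames acquired at a single
exposure time behind a single long-pass filter.  Intensities are detector
counts until :func:`swirquant.correction.normalize_exposure` converts them to
counts/ms; the ``unit`` flag records which.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

__all__ = ["ImageStack"]


@dataclass(frozen=True)
class ImageStack:
    """Ordered 2-D intensity frames plus acquisition metadata.

    Parameters
    ----------
    frames
        Array of shape ``(n_frames, rows, cols)``; a single 2-D array is
        promoted to one frame.  Stored as float64.
    exposure_ms
        Exposure time per frame in milliseconds; must be positive.
    cutoff_nm
        Long-pass filter cutoff label (e.g. 900, 1100, 1300) or ``None``.
    unit
        ``"counts"`` (raw) or ``"counts_per_ms"`` (exposure-normalized).
    meta
        Free-form provenance dictionary (correction parameters applied,
        generator seed, ...).  Carried along, never interpreted.
    """

    frames: np.ndarray
    exposure_ms: float = 1.0
    cutoff_nm: Optional[int] = None
    unit: str = "counts"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        arr = np.asarray(self.frames, dtype=np.float64)
        if arr.ndim == 2:
            arr = arr[np.newaxis, ...]
        if arr.ndim != 3:
            raise ValueError(f"frames must be 2-D or 3-D, got ndim={arr.ndim}")
        if arr.shape[1] == 0 or arr.shape[2] == 0:
            raise ValueError(f"frames have empty spatial extent {arr.shape[1:]}")
        if not np.all(np.isfinite(arr)):
            raise ValueError("frame intensities must be finite")
        if not (np.isfinite(self.exposure_ms) and self.exposure_ms > 0):
            raise ValueError(f"exposure_ms must be > 0, got {self.exposure_ms}")
        object.__setattr__(self, "frames", arr)

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1], self.frames.shape[2]

    def frame(self, index: int) -> np.ndarray:
        """Return frame ``index`` (negative indices allowed)."""
        return self.frames[index]

    def with_frames(self, frames: np.ndarray, **meta_updates) -> "ImageStack":
        """Copy of this stack with new pixel data; metadata is preserved and
        ``meta`` is updated with ``meta_updates``."""
        new_meta = {**self.meta, **meta_updates}
        return replace(self, frames=frames, meta=new_meta)
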