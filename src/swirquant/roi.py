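"""ROI statistics and dB-scale detection metrics.

SNR and CNR follow the decibel convention used throughout fluorescence-guided
surgery work:

    SNR_dB = 10 * log10(mu_signal / sigma_noise)
    CNR_dB = 10 * log10((mu_signal - mu_background) / sigma_background)

with default sufficiency thresholds of 5 dB for detection (SNR) and 3 dB for
delineation (CNR, the Rose criterion).  ROI means and standard deviations are
sample statistics (n-1 denominator) over the selected pixels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .stack import ImageStack

__all__ = [
    "SNR_THRESHOLD_DB",
    "CNR_THRESHOLD_DB",
    "ROI",
    "ROIStats",
    "DbResult",
    "roi_stats",
    "snr_db",
    "cnr_db",
    "organ_table",
    "organ_ratios",
    "rank_organs",
]

#: Default detection-sufficiency threshold for SNR.
SNR_THRESHOLD_DB: float = 5.0
#: Default delineation threshold for CNR (Rose criterion).
CNR_THRESHOLD_DB: float = 3.0


@dataclass(frozen=True)
class ROI:
    """A pixel-selection region on a frame.

    ``kind`` is one of ``"rectangle"`` (params r0, r1, c0, c1; half-open,
    0-based), ``"ellipse"`` (params center_row, center_col, semi_row,
    semi_col; a pixel belongs if its center lies inside) or ``"mask"``
    (params: explicit boolean array under key ``mask``).
    ``frame_index`` selects which frame the ROI refers to; ``None`` means
    "whatever frame the caller designates" (per-frame use).
    """

    kind: str
    params: dict
    label: str = ""
    frame_index: Optional[int] = None

    # -- constructors -----------------------------------------------------
    @classmethod
    def rectangle(cls, r0: int, r1: int, c0: int, c1: int, label: str = "",
                  frame_index: Optional[int] = None) -> "ROI":
        return cls("rectangle", {"r0": r0, "r1": r1, "c0": c0, "c1": c1},
                   label, frame_index)

    @classmethod
    def ellipse(cls, center_row: float, center_col: float, semi_row: float,
                semi_col: float, label: str = "",
                frame_index: Optional[int] = None) -> "ROI":
        return cls("ellipse", {"center_row": center_row, "center_col": center_col,
                               "semi_row": semi_row, "semi_col": semi_col},
                   label, frame_index)

    @classmethod
    def from_mask(cls, mask: np.ndarray, label: str = "",
                  frame_index: Optional[int] = None) -> "ROI":
        mask = np.asarray(mask, dtype=bool)
        if mask.ndim != 2:
            raise ValueError("mask ROI must be a 2-D boolean array")
        return cls("mask", {"mask": mask}, label, frame_index)

    # -- geometry ---------------------------------------------------------
    def mask(self, frame_shape: tuple[int, int]) -> np.ndarray:
        """Boolean pixel mask of this ROI on a frame of ``frame_shape``.

        Raises ``ValueError`` if the ROI is empty or out of bounds.
        """
        rows, cols = frame_shape
        if self.kind == "rectangle":
            p = self.params
            r0, r1, c0, c1 = int(p["r0"]), int(p["r1"]), int(p["c0"]), int(p["c1"])
            if not (0 <= r0 < r1 <= rows and 0 <= c0 < c1 <= cols):
                raise ValueError(
                    f"rectangle [{r0}:{r1}, {c0}:{c1}] outside {frame_shape} or empty")
            m = np.zeros(frame_shape, dtype=bool)
            m[r0:r1, c0:c1] = True
        elif self.kind == "ellipse":
            p = self.params
            if p["semi_row"] <= 0 or p["semi_col"] <= 0:
                raise ValueError("ellipse semi-axes must be positive")
            rr, cc = np.ogrid[:rows, :cols]
            m = (((rr - p["center_row"]) / p["semi_row"]) ** 2
                 + ((cc - p["center_col"]) / p["semi_col"]) ** 2) <= 1.0
        elif self.kind == "mask":
            m = self.params["mask"]
            if m.shape != frame_shape:
                raise ValueError(
                    f"mask ROI shape {m.shape} does not match frame {frame_shape}")
        else:
            raise ValueError(f"unknown ROI kind {self.kind!r}")
        if not m.any():
            raise ValueError(f"ROI {self.label or self.kind!r} selects no pixels")
        return m

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        params = dict(self.params)
        if self.kind == "mask":
            params["mask"] = np.asarray(params["mask"], dtype=bool).tolist()
        return {"label": self.label, "type": self.kind,
                "frame": self.frame_index, "params": params}

    @classmethod
    def from_dict(cls, d: dict) -> "ROI":
        kind = d["type"]
        params = dict(d["params"])
        if kind == "mask":
            params["mask"] = np.asarray(params["mask"], dtype=bool)
        return cls(kind, params, d.get("label", ""), d.get("frame"))


@dataclass(frozen=True)
class ROIStats:
    """Sample mean, sample SD (n-1) and pixel count of an ROI."""

    mean: float
    sd: float
    n_pixels: int

    def __post_init__(self) -> None:
        if self.n_pixels < 1:
            raise ValueError("ROIStats requires at least one pixel")
        if self.n_pixels >= 2 and not (self.sd >= 0):
            raise ValueError("sd must be non-negative")


@dataclass(frozen=True)
class DbResult:
    """A dB-scale metric with its sufficiency call.

    ``defined`` is False when the quantity has no dB value (non-positive
    argument of the log); ``value_db`` is then NaN and ``sufficient`` False.
    """

    value_db: float
    sufficient: bool
    threshold_db: float
    defined: bool = True
    metric: str = ""

    @property
    def linear(self) -> float:
        return 10.0 ** (self.value_db / 10.0)


def roi_stats(stack: ImageStack, roi: ROI, frame_index: Optional[int] = None) -> ROIStats:
    """Sample mean/SD over the ROI pixels of one frame.

    ``frame_index`` overrides the ROI's own ``frame_index`` (default frame 0
    when neither is given).  SD uses the n-1 denominator and requires at
    least two pixels.
    """
    idx = frame_index if frame_index is not None else (roi.frame_index or 0)
    frame = stack.frame(idx)
    values = frame[roi.mask(stack.frame_shape)]
    n = int(values.size)
    mean = float(values.mean())
    if n >= 2:
        sd = float(values.std(ddof=1))
    else:
        raise ValueError(
            f"ROI {roi.label or roi.kind!r} has a single pixel; SD undefined")
    return ROIStats(mean=mean, sd=sd, n_pixels=n)


def snr_db(signal: ROIStats, noise: ROIStats,
           threshold_db: float = SNR_THRESHOLD_DB) -> DbResult:
    """Signal-to-noise ratio in dB: ``10*log10(signal.mean / noise.sd)``.

    Raises ``ValueError`` on non-positive signal mean or noise SD, for which
    the ratio is undefined.
    """
    if not noise.sd > 0:
        raise ValueError(f"noise SD must be positive, got {noise.sd}")
    if not signal.mean > 0:
        raise ValueError(f"signal mean must be positive, got {signal.mean}")
    value = 10.0 * math.log10(signal.mean / noise.sd)
    return DbResult(value, value > threshold_db, threshold_db, metric="snr")


def cnr_db(signal: ROIStats, background: ROIStats,
           threshold_db: float = CNR_THRESHOLD_DB) -> DbResult:
    """Contrast-to-noise ratio in dB.

    ``10*log10((signal.mean - background.mean) / background.sd)``.  When the
    signal mean does not exceed the background mean the contrast is undefined
    (not negative-infinite): the result is flagged ``defined=False`` with a
    NaN value.  Zero background SD is an error.
    """
    if not background.sd > 0:
        raise ValueError(f"background SD must be positive, got {background.sd}")
    diff = signal.mean - background.mean
    if diff <= 0:
        return DbResult(float("nan"), False, threshold_db, defined=False,
                        metric="cnr")
    value = 10.0 * math.log10(diff / background.sd)
    return DbResult(value, value > threshold_db, threshold_db, metric="cnr")


# ---------------------------------------------------------------------------
# Biodistribution organ tables

def organ_table(records: Iterable[tuple[str, float]], unit: str = "mean_intensity") -> pd.DataFrame:
    """Build a validated organ table (columns ``organ``, ``intensity``).

    Labels must be unique and intensities non-negative.
    """
    df = pd.DataFrame(list(records), columns=["organ", "intensity"])
    if df.empty:
        raise ValueError("organ table is empty")
    if df["organ"].duplicated().any():
        dupes = df.loc[df["organ"].duplicated(), "organ"].tolist()
        raise ValueError(f"duplicate organ labels: {dupes}")
    if (df["intensity"] < 0).any():
        raise ValueError("organ intensities must be non-negative")
    df.attrs["unit"] = unit
    return df


def organ_ratios(table: pd.DataFrame, numerator: str,
                 denominators: Sequence[str]) -> pd.DataFrame:
    """Numerator-organ intensity divided by each denominator's intensity.

    Returns a frame with columns ``numerator``, ``denominator``, ``ratio``.
    Missing labels or non-positive denominator intensities are errors.
    """
    lookup = dict(zip(table["organ"], table["intensity"]))
    missing = [lab for lab in [numerator, *denominators] if lab not in lookup]
    if missing:
        raise KeyError(f"labels not in organ table: {missing}")
    num = lookup[numerator]
    rows = []
    for den in denominators:
        if not lookup[den] > 0:
            raise ValueError(f"denominator organ {den!r} has non-positive intensity")
        rows.append({"numerator": numerator, "denominator": den,
                     "ratio": num / lookup[den]})
    return pd.DataFrame(rows)


def rank_organs(table: pd.DataFrame) -> list[str]:
    """Organ labels sorted by decreasing intensity; ties broken alphabetically."""
    if table.empty:
        raise ValueError("organ table is empty")
    ordered = table.sort_values(["intensity", "organ"],
                                ascending=[False, True], kind="mergesort")
    return ordered["organ"].tolist()
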