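"""Longitudinal wound-monitoring metrics.

Wound healing runs contrast in reverse: dye accumulates in the fresh wound,
CNR rises to a peak around two days post injection and then decays as the
wound closes, until the wound is no longer detectable (CNR below the 3 dB
threshold, or undefined).  A bandage attenuates the optical signal but not
the electronic noise floor, so imaging through it lowers CNR and can flip a
timepoint from sufficient to insufficient.

A wound series is a tidy table with one row per timepoint:
``time_h, cnr_db, defined, sufficient, bandage, exposure_ms, cutoff_nm,
subject``.  Undefined CNR values (wound mean at or below background mean)
are retained as flagged rows — "not detectable" is itself the endpoint —
and are treated as below threshold by :func:`healed_time`.
"""

from __future__ import annotations

from dataclasses import dataclass, replace as dc_replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .contrast import contrast_transform
from .roi import CNR_THRESHOLD_DB, ROI, cnr_db, roi_stats
from .stack import ImageStack
from .synthetic import (DEFAULT_WOUND_KINETICS, DEFAULT_WOUND_SPEC,
                        PhantomSpec, WoundKinetics, generate_wound_series,
                        phantom_rois)

__all__ = ["PeakResult", "wound_cnr_series", "peak_time", "healed_time",
           "bandage_effect", "run_wound_experiment", "mean_series"]

SERIES_COLUMNS = ["subject", "time_h", "bandage", "cnr_db", "defined",
                  "sufficient", "exposure_ms", "cutoff_nm"]


@dataclass(frozen=True)
class PeakResult:
    """Timepoint of maximum CNR; ``tie`` marks a non-unique maximum
    (the earliest is reported)."""

    time_h: float
    cnr_db: float
    tie: bool = False


def wound_cnr_series(stacks: Sequence[ImageStack], wound_roi: ROI,
                     background_roi: ROI,
                     threshold_db: float = CNR_THRESHOLD_DB,
                     times_h: Optional[Sequence[float]] = None,
                     subject: str = "") -> pd.DataFrame:
    """Per-timepoint wound CNR from one stack per timepoint.

    Timepoints come from ``times_h`` or from each stack's ``meta['time_h']``
    (as written by the wound generator); a stack with neither is reported by
    its position in an error.  Undefined CNR values are kept as flagged
    rows, never dropped.
    """
    if len(stacks) == 0:
        raise ValueError("no stacks given")
    if times_h is not None and len(times_h) != len(stacks):
        raise ValueError(
            f"{len(times_h)} timepoints for {len(stacks)} stacks")
    missing = [i for i, s in enumerate(stacks)
               if times_h is None and "time_h" not in s.meta]
    if missing:
        raise ValueError(f"stacks at positions {missing} lack a timepoint; "
                         "pass times_h or set meta['time_h']")
    rows = []
    for i, stack in enumerate(stacks):
        t = float(times_h[i]) if times_h is not None else float(stack.meta["time_h"])
        wound = roi_stats(stack, wound_roi, frame_index=0)
        background = roi_stats(stack, background_roi, frame_index=0)
        result = cnr_db(wound, background, threshold_db=threshold_db)
        rows.append({
            "subject": subject,
            "time_h": t,
            "bandage": bool(stack.meta.get("bandage", False)),
            "cnr_db": result.value_db,
            "defined": result.defined,
            "sufficient": result.sufficient,
            "exposure_ms": stack.exposure_ms,
            "cutoff_nm": stack.cutoff_nm,
        })
    df = pd.DataFrame(rows, columns=SERIES_COLUMNS)
    df = df.sort_values("time_h", kind="mergesort").reset_index(drop=True)
    if df["time_h"].duplicated().any():
        raise ValueError("duplicate timepoints in wound series")
    df.attrs["threshold_db"] = threshold_db
    return df


def _defined(series: pd.DataFrame) -> pd.DataFrame:
    if "defined" in series.columns:
        return series[series["defined"] & np.isfinite(series["cnr_db"])]
    return series[np.isfinite(series["cnr_db"])]


def peak_time(series: pd.DataFrame) -> PeakResult:
    """Timepoint of maximum CNR among defined values (ties: earliest, flagged)."""
    defined = _defined(series)
    if defined.empty:
        raise ValueError("no defined CNR values in series")
    best = defined["cnr_db"].max()
    at_best = defined[defined["cnr_db"] == best]
    return PeakResult(time_h=float(at_best["time_h"].iloc[0]),
                      cnr_db=float(best), tie=len(at_best) > 1)


def healed_time(series: pd.DataFrame,
                threshold_db: float = CNR_THRESHOLD_DB) -> Optional[float]:
    """Earliest post-peak timepoint from which CNR stays below threshold.

    Undefined CNR counts as below threshold.  Returns ``None`` when the
    series never settles below threshold after the peak (not reached).  The
    sustained-below rule (all later observations, not the first crossing)
    makes the endpoint robust to a single noisy dip.
    """
    peak = peak_time(series)
    ordered = series.sort_values("time_h", kind="mergesort")
    after = ordered[ordered["time_h"] > peak.time_h]
    if after.empty:
        return None
    below = (~after.get("defined", pd.Series(True, index=after.index)).astype(bool)
             | ~np.isfinite(after["cnr_db"])
             | (after["cnr_db"] < threshold_db))
    # earliest suffix that is below-threshold throughout
    below_rev = below.to_numpy()[::-1]
    run = 0
    for flag in below_rev:
        if flag:
            run += 1
        else:
            break
    if run == 0:
        return None
    return float(after["time_h"].iloc[len(after) - run])


def bandage_effect(with_bandage: pd.DataFrame,
                   without_bandage: pd.DataFrame) -> pd.DataFrame:
    """Per-timepoint CNR reduction caused by the bandage.

    Returns columns ``time_h, cnr_db_without, cnr_db_with, delta_cnr_db,
    sufficiency_flip`` where ``delta_cnr_db = without - with`` and a flip
    marks timepoints delineable without the bandage but not through it.
    Timepoint sets must match exactly.
    """
    t_with = with_bandage["time_h"].to_numpy()
    t_without = without_bandage["time_h"].to_numpy()
    if len(t_with) != len(t_without) or not np.array_equal(np.sort(t_with),
                                                           np.sort(t_without)):
        raise ValueError(
            f"timepoints differ: with={sorted(t_with)}, without={sorted(t_without)}")
    w = with_bandage.sort_values("time_h").reset_index(drop=True)
    wo = without_bandage.sort_values("time_h").reset_index(drop=True)
    delta = wo["cnr_db"].to_numpy() - w["cnr_db"].to_numpy()
    flip = wo["sufficient"].to_numpy() & ~w["sufficient"].to_numpy()
    return pd.DataFrame({
        "time_h": wo["time_h"],
        "cnr_db_without": wo["cnr_db"],
        "cnr_db_with": w["cnr_db"],
        "delta_cnr_db": delta,
        "sufficiency_flip": flip,
    })


# ---------------------------------------------------------------------------
# Synthetic wound experiment

def run_wound_experiment(kinetics: WoundKinetics = DEFAULT_WOUND_KINETICS,
                         spec: PhantomSpec = DEFAULT_WOUND_SPEC,
                         n_subjects: int = 4, seed: int = 0,
                         bandage: bool = False,
                         threshold_db: float = CNR_THRESHOLD_DB) -> pd.DataFrame:
    """Generate and quantify the default synthetic wound experiment.

    One cohort of ``n_subjects`` simulated subjects imaged at the study
    timepoints; per-subject noise seeds derive from ``seed``.  The wound and
    background ROIs come from the phantom ground truth.  Returns the
    concatenated per-subject tidy series.
    """
    wound_roi, background_roi = phantom_rois(spec)
    frames = []
    for subj in range(n_subjects):
        subj_seed = int(np.random.SeedSequence([seed, subj]).generate_state(1)[0]
                        % 2 ** 31)
        subj_spec = dc_replace(spec, seed=subj_seed)
        stacks, _ = generate_wound_series(kinetics, subj_spec, bandage=bandage)
        series = wound_cnr_series(stacks, wound_roi, background_roi,
                                  threshold_db=threshold_db,
                                  subject=f"sim{subj + 1}")
        frames.append(series)
    out = pd.concat(frames, ignore_index=True)
    out.attrs["threshold_db"] = threshold_db
    return out


def mean_series(cohort: pd.DataFrame,
                threshold_db: float = CNR_THRESHOLD_DB) -> pd.DataFrame:
    """Aggregate a multi-subject cohort into a mean dB series per timepoint.

    Averaging happens in dB (after log conversion), matching how cohort
    curves are plotted; undefined values are excluded from the mean and a
    timepoint with no defined value stays flagged undefined.
    """
    rows = []
    for t, group in cohort.groupby("time_h"):
        defined = group[group["defined"] & np.isfinite(group["cnr_db"])]
        if defined.empty:
            rows.append({"time_h": t, "cnr_db": float("nan"), "defined": False,
                         "sufficient": False, "n_subjects": len(group),
                         "sd_db": float("nan")})
        else:
            m = float(defined["cnr_db"].mean())
            sd = float(defined["cnr_db"].std(ddof=1)) if len(defined) > 1 else 0.0
            rows.append({"time_h": t, "cnr_db": m, "defined": True,
                         "sufficient": m > threshold_db,
                         "n_subjects": len(group), "sd_db": sd})
    return pd.DataFrame(rows).sort_values("time_h").reset_index(drop=True)
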