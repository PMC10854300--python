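"""Wound CNR time series: peak detection, healed-endpoint rule and the
effect of imaging through a bandage."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from swirquant import (WoundKinetics, bandage_effect, generate_wound_series,
                       healed_time, mean_series, peak_time,
                       run_wound_experiment, wound_cnr_series)
from swirquant.synthetic import DEFAULT_WOUND_SPEC, phantom_rois


def series_from_pairs(pairs, bandage=False, subject="m1") -> pd.DataFrame:
    rows = [{"subject": subject, "time_h": t, "bandage": bandage,
             "cnr_db": v, "defined": v is not None and np.isfinite(v),
             "sufficient": v is not None and np.isfinite(v) and v > 3.0,
             "exposure_ms": 10.0, "cutoff_nm": 1300}
            for t, v in pairs]
    for row in rows:
        if row["cnr_db"] is None:
            row["cnr_db"] = float("nan")
    return pd.DataFrame(rows)


class TestWoundCnrSeries:
    def test_zero_amplitude_series_all_undefined_or_insufficient(self):
        spec = dataclasses.replace(DEFAULT_WOUND_SPEC, shot_noise=False,
                                   read_noise_sd=1.0)
        kinetics = WoundKinetics(peak_amplitude=0.0, timepoints=(2.0, 24.0, 48.0))
        stacks, _ = generate_wound_series(kinetics, spec)
        wound_roi, bg_roi = phantom_rois(spec)
        series = wound_cnr_series(stacks, wound_roi, bg_roi)
        assert len(series) == 3
        assert not series["sufficient"].any()

    def test_single_timepoint_series(self):
        kinetics = WoundKinetics(timepoints=(48.0,))
        stacks, _ = generate_wound_series(kinetics, DEFAULT_WOUND_SPEC)
        wound_roi, bg_roi = phantom_rois(DEFAULT_WOUND_SPEC)
        series = wound_cnr_series(stacks, wound_roi, bg_roi)
        assert len(series) == 1
        assert series["defined"].iloc[0]

    def test_missing_timepoint_metadata_reported(self):
        from swirquant import ImageStack, ROI
        stack = ImageStack(np.random.default_rng(0).normal(100, 5, (16, 16)))
        with pytest.raises(ValueError, match=r"positions \[0\]"):
            wound_cnr_series([stack], ROI.rectangle(0, 4, 0, 4),
                             ROI.rectangle(8, 12, 8, 12))

    def test_generated_series_unimodal_within_noise(self):
        cohort = run_wound_experiment(n_subjects=2, seed=3)
        mean = mean_series(cohort)
        values = mean["cnr_db"].to_numpy()
        peak_idx = int(np.argmax(values))
        assert np.all(np.diff(values[:peak_idx + 1]) > -0.5)
        assert np.all(np.diff(values[peak_idx:]) < 0.5)


class TestPeakTime:
    def test_argmax_of_explicit_series(self):
        series = series_from_pairs([(2, 1.0), (24, 4.0), (48, 6.0), (72, 5.0)])
        assert peak_time(series).time_h == 48.0

    def test_monotone_decreasing_peaks_at_first_timepoint(self):
        series = series_from_pairs([(2, 6.0), (24, 5.0), (48, 4.0)])
        assert peak_time(series).time_h == 2.0

    def test_tie_earliest_and_flagged(self):
        series = series_from_pairs([(2, 3.0), (24, 6.0), (48, 6.0)])
        result = peak_time(series)
        assert result.time_h == 24.0 and result.tie

    def test_all_undefined_rejected(self):
        series = series_from_pairs([(2, None), (24, None)])
        with pytest.raises(ValueError):
            peak_time(series)

    def test_matches_brute_force_on_synthetic_series(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            times = np.sort(rng.choice(np.arange(1, 400), size=6, replace=False))
            values = rng.normal(5, 3, 6)
            series = series_from_pairs(list(zip(times.tolist(), values.tolist())))
            expected = times[int(np.argmax(values))]
            assert peak_time(series).time_h == expected


class TestHealedTime:
    def test_sustained_below_threshold_after_peak(self):
        series = series_from_pairs([(2, 1.0), (24, 4.0), (48, 6.0), (72, 5.0),
                                    (96, 4.0), (168, 2.1), (240, 1.0)])
        assert healed_time(series) == 168.0

    def test_never_below_threshold_not_reached(self):
        series = series_from_pairs([(24, 4.0), (48, 6.0), (72, 5.0)])
        assert healed_time(series) is None

    def test_dip_and_reexceed_heals_after_last_exceedance(self):
        series = series_from_pairs([(24, 6.0), (48, 2.0), (72, 4.0),
                                    (96, 1.0), (168, 0.5)])
        # brute force over suffixes: 48 dips but 72 re-exceeds -> healed at 96
        assert healed_time(series) == 96.0

    def test_undefined_counts_as_below_threshold(self):
        series = series_from_pairs([(24, 6.0), (48, None), (72, None)])
        assert healed_time(series) == 48.0

    def test_healed_time_not_before_peak_time(self):
        rng = np.random.default_rng(21)
        for _ in range(25):
            times = np.sort(rng.choice(np.arange(1, 300), size=7, replace=False))
            values = rng.normal(3, 2.5, 7)
            series = series_from_pairs(list(zip(times.tolist(), values.tolist())))
            healed = healed_time(series)
            if healed is not None:
                assert healed >= peak_time(series).time_h


class TestBandageEffect:
    def test_identical_series_all_zero(self):
        series = series_from_pairs([(24, 5.0), (48, 7.0)])
        effect = bandage_effect(series, series.copy())
        assert np.allclose(effect["delta_cnr_db"], 0.0)
        assert not effect["sufficiency_flip"].any()

    def test_unmatched_timepoints_rejected(self):
        a = series_from_pairs([(24, 5.0)])
        b = series_from_pairs([(48, 5.0)])
        with pytest.raises(ValueError):
            bandage_effect(a, b)

    def test_attenuation_reduces_cnr_at_every_defined_timepoint(self):
        """Attenuated photon signal over a constant electronic noise floor:
        the bandage must cost contrast everywhere."""
        spec = dataclasses.replace(DEFAULT_WOUND_SPEC, shot_noise=False,
                                   read_noise_sd=5.0, attenuation=0.5, seed=2)
        kinetics = WoundKinetics(timepoints=(24.0, 48.0, 96.0))
        wound_roi, bg_roi = phantom_rois(spec)
        with_b, _ = generate_wound_series(kinetics, spec, bandage=True)
        without_b, _ = generate_wound_series(kinetics, spec, bandage=False)
        sw = wound_cnr_series(with_b, wound_roi, bg_roi)
        swo = wound_cnr_series(without_b, wound_roi, bg_roi)
        effect = bandage_effect(sw, swo)
        assert (effect["delta_cnr_db"] > 0).all()

    def test_late_timepoint_sufficiency_flip(self):
        """At a late, low-amplitude timepoint the wound stays delineable
        without the bandage but not through it."""
        with_b = mean_series(run_wound_experiment(seed=0, bandage=True,
                                                  n_subjects=2))
        without_b = mean_series(run_wound_experiment(seed=0, bandage=False,
                                                     n_subjects=2))
        w = with_b.rename(columns={})
        effect = bandage_effect(
            with_b.assign(subject="cohort", bandage=True),
            without_b.assign(subject="cohort", bandage=False))
        late = effect[effect["time_h"] == 168.0].iloc[0]
        assert late["sufficiency_flip"]

    def test_cnr_non_increasing_in_attenuation_strength(self):
        """Measured CNR falls monotonically as bandage transmission drops
        (fixed read noise), over a grid of attenuation values."""
        kinetics = WoundKinetics(timepoints=(48.0,))
        values = []
        for a in (1.0, 0.8, 0.6, 0.4, 0.2):
            spec = dataclasses.replace(DEFAULT_WOUND_SPEC, shot_noise=False,
                                       read_noise_sd=5.0, attenuation=a, seed=6)
            stacks, _ = generate_wound_series(kinetics, spec, bandage=True)
            wound_roi, bg_roi = phantom_rois(spec)
            series = wound_cnr_series(stacks, wound_roi, bg_roi)
            values.append(series["cnr_db"].iloc[0])
        assert all(b < a for a, b in zip(values, values[1:]))


class TestExperiment:
    def test_default_experiment_recovers_48h_peak(self):
        cohort = run_wound_experiment(seed=1)
        assert peak_time(mean_series(cohort)).time_h == 48.0

    def test_sufficient_from_24_to_168_then_healed(self):
        mean = mean_series(run_wound_experiment(seed=1))
        by_time = mean.set_index("time_h")
        assert by_time.loc[[24.0, 48.0, 72.0, 96.0, 168.0], "sufficient"].all()
        assert not by_time.loc[240.0, "sufficient"]
        assert healed_time(mean) == 240.0
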