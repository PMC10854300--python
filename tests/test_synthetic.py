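"""Generator contracts: determinism, truth-mask consistency, noiseless
closed forms and Monte-Carlo consistency of the noisy outputs."""

import dataclasses

import numpy as np
import pytest

from swirquant import (DEFAULT_ORGAN_PROFILE, PhantomSpec, SpectrumSpec,
                       WoundKinetics, generate_biodistribution_table,
                       generate_spectrum, generate_tumor_phantom,
                       generate_wound_series)
from swirquant.synthetic import (DEFAULT_WOUND_SPEC, SATURATION_COUNTS,
                                 scene_counts_per_ms, tumor_profile)


class TestTumorPhantom:
    def test_same_seed_bit_identical(self):
        spec = PhantomSpec(hot_pixel_rate=1e-3, seed=7)
        a, _ = generate_tumor_phantom(spec)
        b, _ = generate_tumor_phantom(spec)
        assert np.array_equal(a.frames, b.frames)

    def test_different_seeds_differ(self):
        a, ta = generate_tumor_phantom(PhantomSpec(hot_pixel_rate=1e-3, seed=1))
        b, tb = generate_tumor_phantom(PhantomSpec(hot_pixel_rate=1e-3, seed=2))
        assert not np.array_equal(a.frames, b.frames)
        assert not np.array_equal(ta.hot_pixel_masks, tb.hot_pixel_masks)

    def test_truth_masks_consistent(self, noisy_phantom):
        _, _, truth = noisy_phantom
        assert np.all(truth.tumor_mask[truth.core_mask])
        assert not np.any(truth.background_mask & truth.tumor_mask)
        assert truth.true_cnr_linear > 0

    def test_no_signal_case_uniform(self, noiseless_spec):
        spec = dataclasses.replace(noiseless_spec, tumor_amplitude=0.0,
                                   attenuation=0.8)
        stack, _ = generate_tumor_phantom(spec)
        expected = 0.8 * spec.exposure_ms * spec.background_level
        assert np.allclose(stack.frames, expected)

    def test_noiseless_tumor_contrast_closed_form(self, noiseless_spec):
        """tumor-mask mean minus background-mask mean equals the exposure-
        scaled mean of the generator's own blob profile."""
        stack, truth = generate_tumor_phantom(noiseless_spec)
        frame = stack.frame(0)
        measured = frame[truth.tumor_mask].mean() - frame[truth.background_mask].mean()
        expected = noiseless_spec.exposure_ms * \
            tumor_profile(noiseless_spec)[truth.tumor_mask].mean()
        assert measured == pytest.approx(expected, rel=1e-12)

    def test_noiseless_pixels_match_analytic_scene(self, noiseless_spec):
        spec = dataclasses.replace(
            noiseless_spec, ambient_artifact=((20.0, 100.0), 5.0, 80.0))
        stack, _ = generate_tumor_phantom(spec)
        expected = spec.attenuation * spec.exposure_ms * scene_counts_per_ms(spec)
        assert np.array_equal(stack.frame(0), expected)

    def test_hot_pixels_at_saturation(self):
        spec = PhantomSpec(hot_pixel_rate=5e-3, seed=3)
        stack, truth = generate_tumor_phantom(spec)
        hot = truth.hot_pixel_masks[0]
        assert hot.any()
        assert np.all(stack.frame(0)[hot] == SATURATION_COUNTS)

    @pytest.mark.parametrize("field, value", [
        ("frame_shape", (0, 64)), ("exposure_ms", 0.0), ("tumor_radius", -1.0),
        ("core_fraction", 1.5), ("attenuation", 0.0), ("hot_pixel_rate", 2.0),
    ])
    def test_invalid_spec_rejected(self, field, value):
        with pytest.raises(ValueError):
            PhantomSpec(**{field: value})

    def test_spec_roundtrips_through_dict(self):
        spec = PhantomSpec(ambient_artifact=((10.0, 20.0), 4.0, 60.0), seed=9)
        assert PhantomSpec.from_dict(spec.to_dict()) == spec


class TestWoundSeries:
    def test_amplitude_law_unimodal_with_peak_at_t_peak(self):
        k = WoundKinetics(t_peak=48.0, shape=1.0, peak_amplitude=32.0)
        t = np.linspace(0.5, 400.0, 2000)
        a = k.amplitude(t)
        assert np.all(a >= 0)
        t_star = t[np.argmax(a)]
        assert t_star == pytest.approx(48.0, abs=0.5)
        assert float(k.amplitude(48.0)) == pytest.approx(32.0)
        # strictly rising before the peak, falling after
        assert np.all(np.diff(a[t < 40]) > 0)
        assert np.all(np.diff(a[t > 56]) < 0)

    def test_single_timepoint_at_peak(self, noiseless_spec):
        k = WoundKinetics(timepoints=(48.0,))
        stacks, amps = generate_wound_series(k, noiseless_spec)
        assert len(stacks) == 1
        assert amps[0] == pytest.approx(k.peak_amplitude)

    def test_bandage_scales_signal_not_dark(self):
        spec = dataclasses.replace(DEFAULT_WOUND_SPEC, shot_noise=False,
                                   read_noise_sd=0.0, dark_offset=50.0)
        k = WoundKinetics(timepoints=(48.0,))
        (on,), _ = generate_wound_series(k, spec, bandage=True)
        (off,), _ = generate_wound_series(k, spec, bandage=False)
        ratio = (on.frame(0) - 50.0) / (off.frame(0) - 50.0)
        assert np.allclose(ratio, spec.attenuation)

    def test_empty_timepoints_rejected(self):
        with pytest.raises(ValueError):
            WoundKinetics(timepoints=())

    def test_timepoints_must_increase(self):
        with pytest.raises(ValueError):
            WoundKinetics(timepoints=(24.0, 24.0))

    def test_healed_wound_indistinguishable_from_background(self):
        """Long after healing the wound region's mean matches the tissue
        background within sampling error at the default noise level."""
        k = WoundKinetics(timepoints=(2000.0,))
        spec = dataclasses.replace(DEFAULT_WOUND_SPEC, seed=11)
        (stack,), amps = generate_wound_series(k, spec)
        assert amps[0] < 1e-6
        from swirquant.synthetic import phantom_rois
        wound_roi, bg_roi = phantom_rois(spec)
        frame = stack.frame(0)
        w = frame[wound_roi.params["mask"]]
        b = frame[bg_roi.params["mask"]]
        se = np.sqrt(w.var(ddof=1) / w.size + b.var(ddof=1) / b.size)
        assert abs(w.mean() - b.mean()) < 4 * se

    def test_series_deterministic_and_paired_across_bandage(self):
        k = WoundKinetics(timepoints=(24.0, 48.0))
        a, _ = generate_wound_series(k, DEFAULT_WOUND_SPEC, bandage=False)
        b, _ = generate_wound_series(k, DEFAULT_WOUND_SPEC, bandage=False)
        for sa, sb in zip(a, b):
            assert np.array_equal(sa.frames, sb.frames)


class TestBiodistributionTable:
    def test_exact_ratio_propagation_noiseless(self):
        table = generate_biodistribution_table({"tumor": 100.0, "muscle": 1.0})
        lookup = dict(zip(table["organ"], table["intensity"]))
        assert lookup["tumor"] / lookup["muscle"] == pytest.approx(100.0)

    def test_ordering_preserved_noiseless(self):
        table = generate_biodistribution_table({"kidney": 30.0, "liver": 5.0})
        lookup = dict(zip(table["organ"], table["intensity"]))
        assert lookup["kidney"] > lookup["liver"]

    def test_monte_carlo_mean_within_three_standard_errors(self):
        noise_sd = 2.0
        draws = [generate_biodistribution_table(DEFAULT_ORGAN_PROFILE,
                                                noise_sd=noise_sd, seed=s)
                 for s in range(1000)]
        tumor = np.array([d.loc[d["organ"] == "tumor", "intensity"].iloc[0]
                          for d in draws])
        se = noise_sd / np.sqrt(len(draws))
        assert abs(tumor.mean() - DEFAULT_ORGAN_PROFILE["tumor"]) < 3 * se

    def test_negative_intensity_rejected(self):
        with pytest.raises(ValueError):
            generate_biodistribution_table({"tumor": 10.0, "muscle": -1.0})

    def test_single_organ_rejected(self):
        with pytest.raises(ValueError):
            generate_biodistribution_table({"tumor": 10.0})


class TestSpectrumGenerator:
    def test_noiseless_argmax_at_peak(self):
        s = generate_spectrum(SpectrumSpec(peak_nm=798.0, noise_sd=0.0))
        assert s.wavelengths[np.argmax(s.values)] == pytest.approx(798.0)

    def test_amplitude_scaling_pointwise(self):
        a = generate_spectrum(SpectrumSpec(amplitude=1.0))
        b = generate_spectrum(SpectrumSpec(amplitude=2.0))
        assert np.allclose(b.values, 2.0 * a.values)

    def test_reproducible_under_seed(self):
        spec = SpectrumSpec(noise_sd=0.05, seed=13)
        assert np.array_equal(generate_spectrum(spec).values,
                              generate_spectrum(spec).values)

    def test_bad_grid_step_rejected(self):
        with pytest.raises(ValueError):
            SpectrumSpec(grid_step_nm=0.0)
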