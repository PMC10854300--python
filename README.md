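# swirquant

Quantification pipeline for shortwave-infrared (SWIR, 900–1700 nm) and
near-infrared (NIR, 650–900 nm) fluorescence imaging, as used in
fluorescence-guided surgery and post-operative wound monitoring with
systemically injected carbocyanine dyes.

It is written for researchers who acquire grayscale image stacks of
dye-labeled tumors or wounds and need reproducible, threshold-based answers
to "is this lesion detectable?" and "can it be delineated from surrounding
tissue?" — plus the supporting measurements around those answers: frame
corrections, full-width-at-half-maximum sharpness profiling, necropsy
biodistribution ratios, spectral solvent shifts and longitudinal wound
tracking. Seeded phantom generators with complete ground truth make every
stage testable without animal data.

## The metrics at the core

For a signal ROI and a user-chosen background/noise reference ROI (sample
mean μ, sample SD σ, n−1 denominator):

```
SNR_dB = 10·log10(μ_signal / σ_noise)                 sufficient when > 5 dB
CNR_dB = 10·log10((μ_signal − μ_bg) / σ_bg)           sufficient when > 3 dB
```

The 3 dB contrast threshold operationalizes the Rose criterion for reliable
detection. The same formula applied per pixel gives the **contrast-mode**
transform: for each frame, the background ROI statistics are recomputed and
every pixel is mapped to

```
PixelNew = 10·log10((PixelOld − ROIAvg) / ROIStd)
```

Pixels at or below the background mean have no defined logarithm and are
excluded via a validity mask; thresholding the valid dB map at 3 dB yields a
binary tumor delineation mask. Because the transform is invariant under any
per-frame gain/offset change, the delineation does not depend on exposure or
amplifier settings.

Upstream corrections mirror standard acquisition practice: dark-count
subtraction (floored at zero), median/MAD despeckle for hot pixels, cropping
and exposure normalization to counts/ms. Downstream modules quantify
tumor-core sharpness (FWHM of line profiles), organ-table ratios
(e.g. tumor:muscle), spectral peak shifts (trapezoid-integrated fold changes,
percent loss of peak optical density), and wound healing as a CNR time
series with peak and healed-endpoint detection.

## Worked example: synthetic wound monitoring

The default synthetic wound experiment images 4 simulated subjects at
2–240 h post injection. Wound dye amplitude follows a unimodal rise–decay
law peaking at 48 h; each timepoint is a noisy SWIR phantom frame and the
wound CNR is measured exactly as it would be on real stacks:

```
$ swirquant wound-simulate --seed 1 --subjects 4
 time_h    cnr_db  defined  sufficient  n_subjects    sd_db
    2.0 -0.012639     True       False           4 0.291051
   24.0  8.763884     True        True           4 0.069758
   48.0  9.570284     True        True           4 0.080578
   72.0  9.171638     True        True           4 0.101007
   96.0  8.271236     True        True           4 0.013240
  168.0  4.229494     True        True           4 0.105034
  240.0 -0.865393     True       False           4 0.360193
peak 9.57 dB at 48 h; healed at 240 h
```

Reading the columns: the wound becomes delineable (> 3 dB) by 24 h, peaks at
48 h at 9.6 dB, decays as healing progresses, and by 240 h contrast is lost —
the healed endpoint. `sd_db` is the between-subject spread of the cohort.

The same library calls are available directly:

```python
import swirquant as sq

cohort = sq.run_wound_experiment(n_subjects=4, seed=1)
mean = sq.mean_series(cohort)
sq.peak_time(mean).time_h      # 48.0
sq.healed_time(mean)           # 240.0
```

Other entry points: `swirquant simulate` (phantom + ground-truth sidecar),
`correct`, `quantify`, `contrast`, `profile`, `wound-track` (manifest-driven
analysis of real TIFF stacks) and `spectra`.

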