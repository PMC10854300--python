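# Methods

This note documents the models, numerical choices and deliberate
limitations behind `swirquant`, in the order data flows through the
package.

## Phantom model

Real acquisitions this package targets are grayscale SWIR frames of a mouse
with a dye-accumulating lesion, taken under ambient light with an InGaAs
sensor behind a long-pass filter. The phantom generator reproduces the
statistical features the quantification code actually depends on, not the
optics of the scene.

**Scene.** A uniform tissue background (`background_level`, counts/ms)
plus a radially symmetric blob. The blob profile is a raised-cosine
plateau: flat at 1 inside `(1 − falloff_fraction)·R`, falling smoothly to 0
at `(1 + falloff_fraction)·R`, with the half-maximum contour exactly at the
nominal radius `R`. A plateau-plus-falloff was chosen over a Gaussian
because lesions in this class of image show a flat bright interior with a
distinct, brighter core rather than a single bell; it also gives FWHM a
crisp ground truth (a noiseless center profile has FWHM exactly `2R`).
Pixels inside `core_fraction·R` are multiplied by `core_boost ≥ 1`,
standing in for the apoptotic core where dye accumulates most. An optional
ambient-reflection artifact (bright disk) and a Gaussian PSF
(`psf_sigma_px`) emulate the reflection spot and photon scatter; a sharper
(longer-wavelength) cutoff corresponds to a smaller PSF.

**Sensor.** Generated counts are
`attenuation · exposure_ms · scene (+ Poisson shot noise) + dark_offset +
Gaussian read noise`, floored at 0, with hot pixels forced to the 16-bit
saturation value 65535 at rate `hot_pixel_rate`. The instrument's true
noise model and bit depth are not public; Poisson-plus-Gaussian over a
constant dark offset is the generic photon-counting sensor model, and is
recorded in every stack's metadata so downstream provenance is explicit.
The `attenuation` factor models bandage transmission and multiplies only
the photon signal — optical loss — never the dark offset or read noise,
which are electronic.

**Ground truth.** Truth masks are geometric: tumor = `r ≤ R`, core =
`r ≤ core_fraction·R`, background = `r ≥ 1.5·R·(1 + falloff_fraction)`
outside the artifact. `true_cnr_linear` is analytic, not re-measured:
mean blob excess over the tumor mask divided by
`sqrt(attenuation·exposure·background_level + read_noise_sd²)`.

**What the phantom does not emulate** — and hence what passing tests do not
show about real data: tissue autofluorescence structure, wavelength-dependent
water absorption, animal motion, vignetting/flat-field error, and spatially
correlated noise. Results on phantoms validate the arithmetic and the
thresholding logic, not biological effect sizes.

## Correction pipeline

* Dark subtraction floors at zero and reports the floored-pixel count;
  the dB math downstream requires non-negative intensities.
* Outlier removal: a pixel deviating from the median of its `(2r+1)²`
  neighborhood by more than `k`× the neighborhood MAD is replaced by that
  median (defaults r=2, k=10). The center pixel is excluded from its own
  neighborhood: with it included, the window median on a steep intensity
  ramp is frequently the center sample itself, which collapses the local
  MAD to zero and falsely flags ordinary gradient pixels. With the
  exclusion the filter removes essentially all saturated pixels, alters
  <0.1% of clean pixels on the default phantom, and is idempotent on its
  own output.
* Rectangles are half-open, 0-based, row-major — one convention everywhere.
* Exposure normalization divides by `exposure_ms` and flips the unit flag
  to counts/ms; it refuses to run twice.

## dB metrics and contrast mode

SNR and CNR use the `10·log10` convention with sample statistics
(n−1 denominator — ROI pixels are a sample). Default sufficiency
thresholds are 5 dB (SNR, detection) and 3 dB (CNR, Rose-criterion
delineation), both configurable. A signal mean at or below the background
mean makes CNR undefined; the package flags it rather than emitting −∞,
because only positive contrast is meaningful for delineation and "not
detectable" is itself an informative state (it is the wound-healing
endpoint).

The contrast-mode transform recomputes the background ROI's mean/SD per
frame (framewise), then maps each pixel through the CNR formula. Pixels at
or below the background mean go into a validity mask and carry NaN in the
dB map; the delineation mask is `valid AND db > threshold`. A fixed-stats
mode reuses one (mean, SD) pair for streaming. The raw threshold mask
keeps isolated speckle (a 2σ threshold passes ~2% of pure-noise pixels);
consumers measuring lesion area should take the connected component at the
lesion, as the tests do.

## Profiles and FWHM

Line profiles are single rows/columns (optional odd moving-average
smoothing, off by default). The FWHM baseline defaults to the profile's
10th percentile — acquisition protocols rarely state a half-max baseline,
so the package picks a robust one and records it. Half-max crossings are
located by linear interpolation (exact for piecewise-linear peaks); a
multimodal profile uses the outermost crossings and is flagged ambiguous;
a peak whose half level is never crossed on one side is an error rather
than a guess.

## Wound kinetics

Wound dye amplitude follows
`A(t) = peak · (t/t_peak)^p · exp(p·(1 − t/t_peak))`,
a gamma-like unimodal law that is zero at t=0, peaks exactly at `t_peak`
and decays exponentially. Once the peak is pinned at `t_peak`, a single
dimensionless shape `p` governs both rise and decay (both rates equal
`p/t_peak`); the two are not independently tunable and the dataclass says
so. Defaults: `t_peak = 48 h`, `p = 1`, imaging timepoints
{2, 24, 48, 72, 96, 168, 240} h, four subjects per cohort.

The default wound phantom (96×96 frame, background 100 counts/ms, 10 ms
exposure, read noise 5 counts, dark offset 100, wound radius 8 px) has a
background noise SD of ≈32 counts, so the default peak amplitude of
32 counts/ms puts the peak linear CNR near 10 (≈10 dB) — a realistic
strong-uptake wound. Bandage transmission defaults to 0.35 (hydrogel
dressing). Under these conditions the synthetic wound is delineable from
24–168 h, peaks at 48 h, is lost by 240 h, and imaging through the bandage
flips the 168 h timepoint from sufficient to insufficient — the behavior
the wound-tracking operations are designed to detect. These sizes also keep
the full simulation comfortably small (seconds on one CPU).

`healed_time` uses a sustained-below rule: the earliest post-peak timepoint
from which CNR stays below threshold for every later observation, treating
undefined values as below. First-crossing rules are fragile under
single-timepoint noise. Cohorts aggregate per-timepoint in dB (after the
log), matching how such curves are plotted; undefined values are excluded
from the mean but never dropped from the table.

## Spectra

Dye bands are modeled as Gaussians parameterized by peak and FWHM. Peak
detection is grid argmax, optionally refined by a 3-point parabola (vertex
clamped to ±half a grid step). Pre-smoothing is available but off by
default — plate-reader spectra are smooth and smoothing shifts asymmetric
peaks; when comparing noisy spectra the shift computation exposes both
knobs so the caller's choice is explicit. Fold change integrates with the
trapezoidal rule over a stated band and degenerates to a pointwise ratio
for sub-step bands. Degradation is percent loss of peak OD against a
reference timepoint on a shared grid.

Fixture constants package the characterization peaks (dextrose 798 nm /
serum 810 nm absorption; dextrose 794 / blood 818 nm absorption and
813 / 838 nm emission in the blood assay; 4× serum intensity increase) so
tests and examples can generate matching synthetic spectra.

## Biodistribution

The organ-table generator adds unclipped Gaussian noise to a non-negative
relative-intensity profile: clipping at zero would bias the Monte-Carlo
mean, so the non-negativity invariant is enforced on the noiseless profile
and `noise_sd` is documented as small relative to the intensities. The
default profile places the tumor brightest, kidney second (renal
clearance), muscle at 1, and fixes the tumor:muscle, tumor:liver and
tumor:spleen ratios at the reference values 99.63, 17.86 and 47.7 used in
the worked examples. Ranking sorts by decreasing intensity with
alphabetical tie-breaks.

## Interfaces and provenance

TIFF stacks carry exposure/cutoff in a JSON sidecar (TIFF tags are
unreliable across writers); HDF5 uses dataset attributes, and the HDF5
reader takes a user-named dataset path rather than guessing an instrument
schema. Every result directory includes `run_metadata.json` with package
versions and the exact parameter values used; the contrast CLI logs the
per-frame background ROI statistics for auditability. All generators are
bit-reproducible from (spec, seed); per-timepoint and per-subject seeds
derive from the top-level seed via `SeedSequence` spawning, so bandage
on/off series of the same subject are paired draws.

## Known limitations

No flat-field or registration correction; no automatic lesion
segmentation (ROIs are user- or truth-supplied); no 2-D radial profiling
or deconvolution; no multi-peak spectral deconvolution or chemical
kinetics; no mixed-effects cohort modeling (mean ± SD only); no GPU or
real-time implementation of the contrast transform.
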