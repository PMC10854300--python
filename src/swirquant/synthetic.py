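"""Seeded phantom generators with full ground truth.

These generators emulate the statistical structure of small-animal SWIR
fluorescence acquisitions so that every downstream operation can be validated
against a known scene:

* a dim, uniform tissue background,
* a bright tumor (or wound) blob with a flat top, a smooth raised-cosine
  falloff whose half-maximum sits exactly at the nominal radius, and an
  optionally boosted apoptotic core,
* an ambient-light reflection artifact (a bright disk away from the tumor),
* hot-pixel outliers at the sensor saturation value,
* a constant dark-count offset, Gaussian read noise and optional Poisson
  shot noise on the photon signal,
* exposure-time scaling and a multiplicative bandage transmission factor,
* a wound whose amplitude rises to a peak near two days and then decays,
* organ tables with tumor >> kidney > other organs, and
* solvent-shifted Gaussian-like dye spectra.

Every generator is deterministic under its seed: identical spec + seed gives
bit-identical output.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .roi import ROI
from .spectra import Spectrum
from .stack import ImageStack

__all__ = [
    "SATURATION_COUNTS",
    "PhantomSpec",
    "PhantomTruth",
    "WoundKinetics",
    "SpectrumSpec",
    "DEFAULT_WOUND_SPEC",
    "DEFAULT_WOUND_KINETICS",
    "DEFAULT_ORGAN_PROFILE",
    "STUDY_TIMEPOINTS_H",
    "tumor_profile",
    "scene_counts_per_ms",
    "generate_tumor_phantom",
    "generate_wound_series",
    "generate_biodistribution_table",
    "generate_spectrum",
    "phantom_rois",
]

#: Saturation value of a 16-bit detector; injected hot pixels take this value.
SATURATION_COUNTS: float = 65535.0

#: Imaging timepoints (hours post injection) of the wound-monitoring protocol.
STUDY_TIMEPOINTS_H: tuple[float, ...] = (2.0, 24.0, 48.0, 72.0, 96.0, 168.0, 240.0)


@dataclass(frozen=True)
class PhantomSpec:
    """Scene and sensor parameters of a single-blob phantom.

    Intensities are photon-signal rates in counts/ms; the generated frame is
    ``attenuation * exposure_ms * scene (+ shot noise) + dark_offset + read
    noise``, with hot pixels then forced to :data:`SATURATION_COUNTS`.

    The blob profile is a raised-cosine plateau: flat at 1 for
    ``r <= (1 - falloff_fraction) * tumor_radius``, falling smoothly to 0 at
    ``(1 + falloff_fraction) * tumor_radius``; the half-maximum contour sits
    exactly at ``tumor_radius``, so the noiseless FWHM of a center profile is
    ``2 * tumor_radius``.  Pixels inside ``core_fraction * tumor_radius`` are
    multiplied by ``core_boost`` (the brighter apoptotic core).
    ``psf_sigma_px`` Gaussian-blurs the noiseless scene to emulate photon
    scatter; sharper long-pass cutoffs correspond to smaller sigma.
    """

    frame_shape: tuple[int, int] = (128, 128)
    background_level: float = 100.0        # counts/ms
    tumor_center: tuple[float, float] = (64.0, 64.0)
    tumor_radius: float = 18.0             # px, half-max radius
    tumor_amplitude: float = 300.0         # counts/ms above background, at plateau
    core_fraction: float = 0.35
    core_boost: float = 1.6
    falloff_fraction: float = 0.3
    ambient_artifact: Optional[tuple[tuple[float, float], float, float]] = None
    hot_pixel_rate: float = 0.0
    dark_offset: float = 100.0             # counts
    read_noise_sd: float = 5.0             # counts
    shot_noise: bool = True
    exposure_ms: float = 10.0
    attenuation: float = 1.0               # bandage transmission
    psf_sigma_px: float = 0.0
    n_frames: int = 1
    cutoff_nm: Optional[int] = 900
    seed: int = 0

    def __post_init__(self) -> None:
        r, c = self.frame_shape
        if r <= 0 or c <= 0:
            raise ValueError(f"frame_shape must be positive, got {self.frame_shape}")
        if not self.tumor_radius > 0:
            raise ValueError("tumor_radius must be > 0")
        if not 0.0 <= self.core_fraction <= 1.0:
            raise ValueError("core_fraction must be in [0, 1]")
        if not 0.0 < self.falloff_fraction < 1.0:
            raise ValueError("falloff_fraction must be in (0, 1)")
        if not self.core_boost >= 1.0:
            raise ValueError("core_boost must be >= 1")
        if not 0.0 < self.attenuation <= 1.0:
            raise ValueError("attenuation must be in (0, 1]")
        if not 0.0 <= self.hot_pixel_rate <= 1.0:
            raise ValueError("hot_pixel_rate must be in [0, 1]")
        if not self.exposure_ms > 0:
            raise ValueError("exposure_ms must be > 0")
        for name in ("background_level", "tumor_amplitude", "dark_offset",
                     "read_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["frame_shape"] = list(self.frame_shape)
        d["tumor_center"] = list(self.tumor_center)
        if self.ambient_artifact is not None:
            center, radius, intensity = self.ambient_artifact
            d["ambient_artifact"] = {"center": list(center), "radius": radius,
                                     "intensity": intensity}
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "PhantomSpec":
        d = dict(d)
        d["frame_shape"] = tuple(d["frame_shape"])
        d["tumor_center"] = tuple(d["tumor_center"])
        art = d.get("ambient_artifact")
        if isinstance(art, Mapping):
            d["ambient_artifact"] = (tuple(art["center"]), art["radius"],
                                     art["intensity"])
        elif art is not None:
            center, radius, intensity = art
            d["ambient_artifact"] = (tuple(center), radius, intensity)
        return cls(**d)


@dataclass(frozen=True)
class PhantomTruth:
    """Ground truth accompanying a generated phantom.

    ``true_cnr_linear`` is the analytic (tumor mean - background mean) /
    background SD of the noise model, not an empirical re-measurement:
    the background SD is ``sqrt(attenuation * exposure * background_level +
    read_noise_sd^2)`` with shot noise on, else ``read_noise_sd``.  It is
    NaN when the configured noise model gives zero background variance.
    ``hot_pixel_masks`` records the injected outliers per frame.
    """

    tumor_mask: np.ndarray
    core_mask: np.ndarray
    background_mask: np.ndarray
    true_cnr_linear: float
    generator_params: PhantomSpec
    hot_pixel_masks: np.ndarray = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if not np.all(self.tumor_mask[self.core_mask]):
            raise AssertionError("core_mask must be a subset of tumor_mask")
        if np.any(self.background_mask & self.tumor_mask):
            raise AssertionError("background_mask must be disjoint from tumor_mask")


@dataclass(frozen=True)
class WoundKinetics:
    """Unimodal rise-then-decay law for wound dye amplitude.

    amplitude(t) = peak_amplitude * (t / t_peak)^shape * exp(shape * (1 - t / t_peak))

    The gamma-like law is zero at t=0, attains ``peak_amplitude`` exactly at
    ``t_peak`` and decays exponentially afterwards.  With the peak position
    pinned, one dimensionless ``shape`` parameter controls both how fast the
    signal rises and how fast it decays; the initial rise and asymptotic
    decay rates both equal ``shape / t_peak`` (per hour).
    """

    t_peak: float = 48.0
    shape: float = 1.0
    peak_amplitude: float = 32.0           # counts/ms
    timepoints: tuple[float, ...] = STUDY_TIMEPOINTS_H

    def __post_init__(self) -> None:
        if not self.t_peak > 0:
            raise ValueError("t_peak must be > 0")
        if not self.shape > 0:
            raise ValueError("shape must be > 0")
        if self.peak_amplitude < 0:
            raise ValueError("peak_amplitude must be >= 0")
        if len(self.timepoints) == 0:
            raise ValueError("timepoints must be non-empty")
        tp = tuple(float(t) for t in self.timepoints)
        if any(t <= 0 for t in tp) or any(b <= a for a, b in zip(tp, tp[1:])):
            raise ValueError("timepoints must be positive and strictly increasing")
        object.__setattr__(self, "timepoints", tp)

    @property
    def rate_per_h(self) -> float:
        """Rise/decay rate ``shape / t_peak`` in 1/h."""
        return self.shape / self.t_peak

    def amplitude(self, t_hours) -> np.ndarray:
        """Evaluate the amplitude law (counts/ms) at ``t_hours`` (scalar or array)."""
        t = np.asarray(t_hours, dtype=np.float64)
        x = t / self.t_peak
        with np.errstate(divide="ignore", invalid="ignore"):
            a = self.peak_amplitude * x ** self.shape * np.exp(self.shape * (1.0 - x))
        a = np.where(t <= 0, 0.0, a)
        return a if a.ndim else float(a)


@dataclass(frozen=True)
class SpectrumSpec:
    """Gaussian-like dye band on a uniform wavelength grid.

    ``width_nm`` is the full width at half maximum of the band; ``noise_sd``
    is additive Gaussian noise in the value unit.
    """

    grid_start_nm: float = 700.0
    grid_stop_nm: float = 900.0
    grid_step_nm: float = 1.0
    peak_nm: float = 798.0
    width_nm: float = 40.0
    amplitude: float = 1.0
    noise_sd: float = 0.0
    label: str = ""
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.grid_step_nm > 0:
            raise ValueError("grid_step_nm must be > 0")
        if not self.width_nm > 0:
            raise ValueError("width_nm must be > 0")
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if self.grid_stop_nm <= self.grid_start_nm:
            raise ValueError("grid_stop_nm must exceed grid_start_nm")


# -- default study conditions ------------------------------------------------

#: Wound phantom: smaller blob, no core boost, hydrogel-bandage transmission.
DEFAULT_WOUND_SPEC = PhantomSpec(
    frame_shape=(96, 96),
    tumor_center=(48.0, 48.0),
    tumor_radius=8.0,
    tumor_amplitude=32.0,
    core_fraction=0.0,
    core_boost=1.0,
    attenuation=0.35,
    cutoff_nm=1300,
)

DEFAULT_WOUND_KINETICS = WoundKinetics()

#: Relative organ fluorescence profile for biodistribution phantoms
#: (arbitrary units, muscle = 1).  Tumor is brightest; residual kidney signal
#: reflects renal clearance; all other organs retain little dye.  The
#: tumor:muscle, tumor:liver and tumor:spleen ratios equal the reported
#: in vivo values by construction.
DEFAULT_ORGAN_PROFILE: dict[str, float] = {
    "tumor": 99.63,
    "kidney": 30.0,
    "liver": 99.63 / 17.86,
    "skin": 4.0,
    "lung": 3.0,
    "spleen": 99.63 / 47.7,
    "heart": 1.8,
    "pancreas": 1.5,
    "intestine": 1.4,
    "muscle": 1.0,
    "brain": 0.5,
}


# -- scene construction ------------------------------------------------------

def _radius_map(spec: PhantomSpec) -> np.ndarray:
    rows, cols = spec.frame_shape
    rr, cc = np.ogrid[:rows, :cols]
    return np.hypot(rr - spec.tumor_center[0], cc - spec.tumor_center[1])


def tumor_profile(spec: PhantomSpec) -> np.ndarray:
    """Noiseless blob profile in counts/ms (before background/artifact/blur).

    Raised-cosine plateau scaled by ``tumor_amplitude`` with the core region
    multiplied by ``core_boost``; half maximum at ``tumor_radius``.
    """
    r = _radius_map(spec)
    r_flat = spec.tumor_radius * (1.0 - spec.falloff_fraction)
    r_zero = spec.tumor_radius * (1.0 + spec.falloff_fraction)
    profile = np.zeros(spec.frame_shape, dtype=np.float64)
    profile[r <= r_flat] = 1.0
    in_falloff = (r > r_flat) & (r < r_zero)
    u = (r[in_falloff] - r_flat) / (r_zero - r_flat)
    profile[in_falloff] = 0.5 * (1.0 + np.cos(np.pi * u))
    if spec.core_fraction > 0 and spec.core_boost > 1:
        profile[r <= spec.core_fraction * spec.tumor_radius] *= spec.core_boost
    return spec.tumor_amplitude * profile


def scene_counts_per_ms(spec: PhantomSpec) -> np.ndarray:
    """Noiseless photon-signal scene in counts/ms: background + blob +
    ambient reflection artifact, blurred by the PSF."""
    scene = np.full(spec.frame_shape, float(spec.background_level))
    scene += tumor_profile(spec)
    if spec.ambient_artifact is not None:
        (ar, ac), radius, intensity = spec.ambient_artifact
        rows, cols = spec.frame_shape
        rr, cc = np.ogrid[:rows, :cols]
        scene[np.hypot(rr - ar, cc - ac) <= radius] += intensity
    if spec.psf_sigma_px > 0:
        scene = ndimage.gaussian_filter(scene, spec.psf_sigma_px, mode="nearest")
    return scene


def _truth_masks(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    r = _radius_map(spec)
    tumor = r <= spec.tumor_radius
    core = r <= spec.core_fraction * spec.tumor_radius
    background = r >= 1.5 * spec.tumor_radius * (1.0 + spec.falloff_fraction)
    if spec.ambient_artifact is not None:
        (ar, ac), radius, _ = spec.ambient_artifact
        rows, cols = spec.frame_shape
        rr, cc = np.ogrid[:rows, :cols]
        background &= np.hypot(rr - ar, cc - ac) > 1.5 * radius
    return tumor, core, background


def _analytic_cnr(spec: PhantomSpec, tumor_mask: np.ndarray) -> float:
    scene = scene_counts_per_ms(spec)
    signal = spec.attenuation * spec.exposure_ms * scene
    bg_counts = spec.attenuation * spec.exposure_ms * spec.background_level
    diff = float(signal[tumor_mask].mean() - bg_counts)
    var = spec.read_noise_sd ** 2 + (bg_counts if spec.shot_noise else 0.0)
    if var == 0:
        return float("nan")
    return diff / float(np.sqrt(var))


def generate_tumor_phantom(spec: PhantomSpec) -> tuple[ImageStack, PhantomTruth]:
    """Simulate an image stack of the phantom scene plus its ground truth.

    Each frame draws independent noise; hot pixels are re-drawn per frame.
    Identical spec (including seed) gives bit-identical stacks.
    """
    scene = scene_counts_per_ms(spec)
    expected = spec.attenuation * spec.exposure_ms * scene
    rng = np.random.default_rng(spec.seed)
    frames = np.empty((spec.n_frames, *spec.frame_shape), dtype=np.float64)
    hot_masks = np.zeros((spec.n_frames, *spec.frame_shape), dtype=bool)
    for i in range(spec.n_frames):
        photon = rng.poisson(expected).astype(np.float64) if spec.shot_noise \
            else expected.copy()
        frame = photon + spec.dark_offset
        if spec.read_noise_sd > 0:
            frame = frame + rng.normal(0.0, spec.read_noise_sd, spec.frame_shape)
        if spec.hot_pixel_rate > 0:
            hot = rng.random(spec.frame_shape) < spec.hot_pixel_rate
            frame[hot] = SATURATION_COUNTS
            hot_masks[i] = hot
        frames[i] = np.clip(frame, 0.0, None)
    stack = ImageStack(frames, exposure_ms=spec.exposure_ms,
                       cutoff_nm=spec.cutoff_nm, unit="counts",
                       meta={"generator": "tumor_phantom",
                             "spec": spec.to_dict()})
    tumor, core, background = _truth_masks(spec)
    truth = PhantomTruth(tumor_mask=tumor, core_mask=core,
                         background_mask=background,
                         true_cnr_linear=_analytic_cnr(spec, tumor),
                         generator_params=spec, hot_pixel_masks=hot_masks)
    return stack, truth


def phantom_rois(spec: PhantomSpec) -> tuple[ROI, ROI]:
    """(signal ROI, background ROI) derived from the phantom's truth masks."""
    tumor, _, background = _truth_masks(spec)
    return (ROI.from_mask(tumor, label="signal"),
            ROI.from_mask(background, label="background"))


def generate_wound_series(
    kinetics: WoundKinetics,
    spec: PhantomSpec = DEFAULT_WOUND_SPEC,
    bandage: bool = False,
) -> tuple[list[ImageStack], list[float]]:
    """One phantom stack per timepoint with the wound amplitude following the
    rise-decay law.

    The bandage multiplies the photon signal (tissue background and wound,
    not the dark offset or read noise) by ``spec.attenuation``; without a
    bandage the transmission is 1.  Noise seeds are derived per timepoint
    from ``spec.seed`` only, so the bandage-on and bandage-off series of one
    subject are paired draws.

    Returns the stacks and the list of true wound amplitudes (counts/ms,
    before bandage attenuation).
    """
    transmission = spec.attenuation if bandage else 1.0
    stacks: list[ImageStack] = []
    amplitudes: list[float] = []
    for i, t in enumerate(kinetics.timepoints):
        amp = float(kinetics.amplitude(t))
        child_seed = int(np.random.SeedSequence([spec.seed, i]).generate_state(1)[0]
                         % 2 ** 31)
        tp_spec = replace(spec, tumor_amplitude=amp, attenuation=transmission,
                          seed=child_seed)
        stack, _ = generate_tumor_phantom(tp_spec)
        stack = stack.with_frames(stack.frames, time_h=t, bandage=bandage)
        stacks.append(stack)
        amplitudes.append(amp)
    return stacks, amplitudes


def generate_biodistribution_table(
    profile: Mapping[str, float],
    noise_sd: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Organ table with Gaussian measurement noise on each mean intensity.

    Noise is additive and unclipped (clipping would bias the sample mean);
    ``noise_sd`` is meant to be small relative to the intensities.
    """
    if len(profile) < 2:
        raise ValueError("profile must contain at least two organs")
    for organ, value in profile.items():
        if value < 0:
            raise ValueError(f"negative intensity for {organ!r}")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    labels = list(profile)
    intensities = np.asarray([profile[k] for k in labels], dtype=np.float64)
    if noise_sd > 0:
        intensities = intensities + rng.normal(0.0, noise_sd, len(labels))
    df = pd.DataFrame({"organ": labels, "intensity": intensities})
    df.attrs["unit"] = "mean_intensity"
    return df


def generate_spectrum(spec: SpectrumSpec) -> Spectrum:
    """Sampled Gaussian band plus additive noise on a uniform grid."""
    wl = np.arange(spec.grid_start_nm, spec.grid_stop_nm + 0.5 * spec.grid_step_nm,
                   spec.grid_step_nm)
    sigma = spec.width_nm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    values = spec.amplitude * np.exp(-0.5 * ((wl - spec.peak_nm) / sigma) ** 2)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        values = values + rng.normal(0.0, spec.noise_sd, wl.size)
    return Spectrum(wl, values, label=spec.label)
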