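import dataclasses

import numpy as np
import pytest

from swirquant import PhantomSpec, generate_tumor_phantom
from swirquant.synthetic import phantom_rois


@pytest.fixture
def noiseless_spec() -> PhantomSpec:
    """Phantom with every noise source disabled: pixels follow the analytic
    scene formula exactly."""
    return PhantomSpec(shot_noise=False, read_noise_sd=0.0, dark_offset=0.0,
                       hot_pixel_rate=0.0, seed=0)


@pytest.fixture
def noisy_phantom():
    """Default noisy phantom stack with its ground truth."""
    spec = PhantomSpec(seed=42)
    return spec, *generate_tumor_phantom(spec)


def spec_with_true_cnr(target_linear: float, **overrides) -> PhantomSpec:
    """Phantom spec whose analytic (tumor mean - background mean) /
    background SD equals ``target_linear``; the analytic CNR is linear in
    the blob amplitude, so one unit-amplitude evaluation fixes the scale."""
    base = PhantomSpec(tumor_amplitude=1.0, hot_pixel_rate=0.0,
                       **{k: v for k, v in overrides.items()
                          if k != "tumor_amplitude"})
    _, truth = generate_tumor_phantom(base)
    return dataclasses.replace(base,
                               tumor_amplitude=target_linear / truth.true_cnr_linear)


def brute_force_roi_stats(frame: np.ndarray, mask: np.ndarray):
    """Independent loop-based mean/SD oracle for ROI statistics."""
    values = [frame[r, c] for r in range(frame.shape[0])
              for c in range(frame.shape[1]) if mask[r, c]]
    n = len(values)
    mean = sum(values) / n
    var = sum((v - mean) ** 2 for v in values) / (n - 1)
    return mean, var ** 0.5, n
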