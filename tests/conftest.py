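import dataclasses

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from avfthrill.core import FrameStack
from avfthrill.synth import SynthParams

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

FS = 40.0


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_params():
    """Small-image, 256-frame recording parameters for fast tests."""
    return SynthParams(rows=24, cols=24, duration_s=6.4, seed=7)


@pytest.fixture
def flat_params(small_params):
    """Spatially flat reflectance (profile == 1 everywhere)."""
    return dataclasses.replace(
        small_params, ridge_amp=0.0, base_reflectance=1.0, halation_count=0
    )


@pytest.fixture
def tone_stack():
    """Planted equal-amplitude 7 Hz and 17 Hz tones, flat profile, no noise.

    Both tones sit 0.8 bins off a 256-point grid, so their Hann scalloping
    losses match.
    """
    t = np.arange(400) / FS
    wave = np.sin(2 * np.pi * 7.0 * t) + np.sin(2 * np.pi * 17.0 * t)
    return FrameStack(np.tile(wave[:, None, None], (1, 8, 8)), fps=FS)
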