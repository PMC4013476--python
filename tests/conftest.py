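"""Shared fixtures: small-image conditions keep Monte-Carlo tests fast while
preserving every structural property of the full 256-pixel stimuli."""

import numpy as np
import pytest

import freeloc as fl
from freeloc.simulate import LocalizationEngine

SMALL_SHAPE = 64


@pytest.fixture(scope="session")
def target3():
    return fl.TargetSpec(sigma_pixels=3.0)


@pytest.fixture(scope="session")
def noise_b1():
    return fl.NoiseSpec(beta=1.0, shape=SMALL_SHAPE)


@pytest.fixture(scope="session")
def spectrum_b1(noise_b1):
    return fl.build_spectrum(noise_b1)


@pytest.fixture(scope="session")
def engine_b1(noise_b1, target3):
    return LocalizationEngine(noise_b1, target3, radius_px=5)


@pytest.fixture(scope="session")
def lut_b1(noise_b1):
    """Localization IO look-up table for beta=1 at the small image size."""
    return fl.simulate_lut("localization", 1.0, n_per_point=1000, step=0.02,
                           seed=11, shape=SMALL_SHAPE)


def binom_se(p: float, n: int) -> float:
    return np.sqrt(max(p * (1 - p), 1e-12) / n)
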