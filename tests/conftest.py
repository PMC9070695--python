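import numpy as np
import pytest

from streakless.normalization import ProjectionStack
from streakless.synthetic import SyntheticConfig, corrupt, make_phantom_projections

FIXTURE_SHAPE = (64, 96, 64)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def phantom_cache():
    """Session cache of phantom projections keyed by (peak, seed, shape)."""
    cache = {}

    def get(peak=np.inf, seed=2, shape=FIXTURE_SHAPE):
        key = (peak, seed, shape)
        if key not in cache:
            cfg = SyntheticConfig(shape=shape, peak=peak, seed=seed)
            cache[key] = make_phantom_projections(cfg)
        return cache[key]

    return get


@pytest.fixture(scope="session")
def noisy_fixture(phantom_cache):
    """Factory for corrupted fixtures: returns (Z, Y, lnA, cfg)."""

    def make(peak=np.inf, sigma_w=0.02, sigma_u=0.0, sigma_v=0.0, seed=2, shape=FIXTURE_SHAPE):
        cfg = SyntheticConfig(
            shape=shape, peak=peak, sigma_w=sigma_w, sigma_u=sigma_u, sigma_v=sigma_v, seed=seed
        )
        A = phantom_cache(peak=peak, seed=seed, shape=shape)
        Z, Y, lnA = corrupt(A, cfg)
        return Z, Y, lnA, cfg

    return make


@pytest.fixture
def small_stack(rng):
    return ProjectionStack(data=rng.standard_normal((16, 24, 20)))


def identity_denoiser(volume, psd, profile):
    """Injectable denoiser that returns its input unchanged."""
    return np.asarray(volume, dtype=np.float64)
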