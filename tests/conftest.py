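import numpy as np
import pytest

from seedvigor import PhantomConfig


@pytest.fixture
def small_cfg() -> PhantomConfig:
    """A phantom small enough to render in well under a second."""
    return PhantomConfig(seeds_per_class=3, image_width=120, image_lines=120,
                         rng_seed=7)


@pytest.fixture
def clean_cfg() -> PhantomConfig:
    """Noise-free, jitter-free phantom: spectra are exactly affine in the
    class endmembers (for exactness tests)."""
    return PhantomConfig(seeds_per_class=3, image_width=120, image_lines=120,
                         noise_sd=0.0, spectral_noise_sd=0.0,
                         depth_jitter_sd=0.0, rng_seed=7)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
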