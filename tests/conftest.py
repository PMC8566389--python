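import numpy as np
import pytest

from glioprog.synthdata import CohortConfig, EffectSizes, generate_case


def noise_free_config(**overrides) -> CohortConfig:
    """Small, fully deterministic study conditions: no voxel noise, no
    between-case dispersion, no B0 inhomogeneity."""
    defaults = dict(
        n_pd=2, n_trc=2, grid_shape=(32, 32, 32), seed=7,
        effect_sd=EffectSizes(0.0, 0.0, 0.0),
        fet_noise_sd=0.0, dsc_noise_sd=0.0, zspec_noise_sd=0.0,
        b0_offset_sd_ppm=0.0, b0_gradient_sd_ppm=0.0,
    )
    defaults.update(overrides)
    return CohortConfig(**defaults)


@pytest.fixture(scope="session")
def clean_pd_case():
    """A noise-free PD case with the canonical planted effects
    (TBR 3, rCBV 8%, APTw 3%)."""
    return generate_case(noise_free_config(), "PD", 0)


@pytest.fixture(scope="session")
def noisy_pd_case():
    """A PD case at the default noise levels on a small grid."""
    return generate_case(CohortConfig(grid_shape=(32, 32, 32)), "PD", 3)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
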