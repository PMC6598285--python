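import pytest

from plexquant.quant import PurityMatrix
from plexquant.simulate import SyntheticConfig, generate_dataset


@pytest.fixture(scope="session")
def noise_free_config():
    """Idealized generator settings: no noise, no defects, no channel leakage."""
    return SyntheticConfig(
        n_proteins=30,
        psm_min=10,
        psm_max=10,
        noise_sd_log2=0.0,
        frac_zero_channel=0.0,
        frac_low_quality=0.0,
        frac_unlabeled=0.0,
        frac_offdb=0.0,
        frac_low_intensity=0.0,
        seed=7,
    )


@pytest.fixture(scope="session")
def noise_free_data(noise_free_config):
    return generate_dataset(noise_free_config)


@pytest.fixture(scope="session")
def default_purity():
    return PurityMatrix.default()
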