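import numpy as np
import pytest

from coexmap.synthetic import SyntheticConfig, generate_study


@pytest.fixture(scope="session")
def tiny_config() -> SyntheticConfig:
    """A small but fully functional study: 4x4x4 grid, 5 genes, 1 driver."""
    return SyntheticConfig(
        n_sites=64,
        spacing_mm=2.0,
        n_genes=5,
        n_drivers=1,
        n_wells=28,
        noise_sd=0.0,
        field_range=10.0,
        field_family="gaussian",
        seed=7,
    )


@pytest.fixture(scope="session")
def tiny_study(tiny_config):
    """(domain, fields, target, drivers, samples) for the tiny config."""
    return generate_study(tiny_config)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20260928)
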