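import logging

import numpy as np
import pytest

from milknir import (LONGWAVE, SHORTWAVE, SimulationConfig, SpectralBlock,
                     simulate_dataset)

logging.getLogger("milknir").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240810)


@pytest.fixture(scope="session")
def default_dataset():
    """One default 45-sample two-instrument simulation (seed 0)."""
    return simulate_dataset(SimulationConfig(seed=0))


@pytest.fixture(scope="session")
def noise_free_config():
    return SimulationConfig(seed=7)


@pytest.fixture(scope="session")
def quiet_profiles():
    """Instrument profiles with every noise source disabled."""
    import dataclasses
    return (dataclasses.replace(SHORTWAVE, noise_sd=0.0, scatter_sd=0.0),
            dataclasses.replace(LONGWAVE, noise_sd=0.0, scatter_sd=0.0))


def random_block(rng, n=8, p=12, instrument="test") -> SpectralBlock:
    wavelengths = np.linspace(800.0, 1000.0, p)
    return SpectralBlock(instrument, wavelengths, rng.normal(size=(n, p)),
                         [f"S{i:02d}" for i in range(n)])
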