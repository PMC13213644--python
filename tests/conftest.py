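import numpy as np
import pytest

from hsichem import (
    SimulationConfig,
    planted_band_design,
    simulate_feature_table,
    simulate_spectrum_set,
)


@pytest.fixture(scope="session")
def spectrum_set():
    """Default-condition spectrum set (87/30/30 samples, 270 bands)."""
    return simulate_spectrum_set(SimulationConfig(seed=11))


@pytest.fixture(scope="session")
def small_spectrum_set():
    return simulate_spectrum_set(
        SimulationConfig(samples_per_class=(12, 6, 6), seed=2)
    )


@pytest.fixture(scope="session")
def planted_design():
    """270-band regression design with 10 planted informative bands."""
    X, y, planted = planted_band_design(seed=3)
    return X, y, planted


@pytest.fixture(scope="session")
def feature_table():
    """Default planted metabolomics table (FC = 4, 40 planted features)."""
    return simulate_feature_table(seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
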