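import numpy as np
import pytest

from swampdendro.ringio import RingSeries
from swampdendro.synthetic_data import SimulationConfig, SpeciesConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def negexp_series():
    """A noiseless negative-exponential series, 300 years."""
    ages = np.arange(1, 301)
    widths = 3.0 * np.exp(-ages / 40.0) + 0.3
    return RingSeries(series_id="NEGX01", species_code="TST",
                      first_year=1700, widths=widths)


def make_common_signal_config(seed, n_trees=20, beta=1.0, noise=0.3,
                              common=0.0):
    """Single-species set sharing a summer water-depth signal."""
    return SimulationConfig(seed=seed, species=[SpeciesConfig(
        code="TST", n_trees=n_trees, birth_range=(1880, 1930),
        w0=2.0, decay=40.0, asymptote=1.0,
        sensitivity={"water_depth:6-9": beta},
        noise_sigma=noise, common_sigma=common,
    )])


@pytest.fixture
def common_signal_config():
    return make_common_signal_config(seed=7)
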