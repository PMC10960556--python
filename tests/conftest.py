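import numpy as np
import pytest

from cset.synthetic import make_scenario


@pytest.fixture(scope="session")
def small_scenario():
    """Fast shared scenario: 120 vertices, 24 sensors, 3 active harmonics."""
    return make_scenario(n_vertices=120, n_sensors=24, k_active=3, snr_db=3.0, seed=7)


@pytest.fixture(scope="session")
def small_signed_scenario():
    """Small scenario with exactly-sparse signed spectral truth."""
    return make_scenario(
        n_vertices=120, n_sensors=24, k_active=3, snr_db=3.0, seed=7,
        nonnegative=False,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
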