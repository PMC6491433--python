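import numpy as np
import pytest

from osmoswitch import fixtures, synthetic


@pytest.fixture(scope="session")
def standard_decay():
    """Bi-exponential TCSPC fixture at the recorded 10^4 peak count."""
    return synthetic.simulate_decay([5.0, 1.0], [0.6, 0.4], irf_fwhm_ns=0.5,
                                    peak_count=10_000, seed=42)


@pytest.fixture(scope="session")
def conditions():
    return fixtures.load_conditions()


@pytest.fixture(scope="session")
def titrant_grid():
    return synthetic.default_titrant_grid()


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
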