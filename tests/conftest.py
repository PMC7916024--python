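import numpy as np
import pytest

from comorbsig import SynthSpec, simulate_all


@pytest.fixture(scope="session")
def default_sim():
    """One full synthetic study at the default desk-scale design, seed 1."""
    return simulate_all(SynthSpec(), seed=1)


@pytest.fixture(scope="session")
def truth(default_sim):
    return default_sim["truth"]


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
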