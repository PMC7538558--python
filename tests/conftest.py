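import numpy as np
import pytest

from rgcmodes.population import build_population
from rgcmodes.stimuli import make_grating_sequence


@pytest.fixture(scope="session")
def grating():
    """2-s drifting square grating at the middle spatial frequency."""
    return make_grating_sequence(0.0, 0.023, duration_s=2.0)


@pytest.fixture(scope="session")
def small_population():
    return build_population(16, seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
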