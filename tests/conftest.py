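import numpy as np
import pytest

from abquant.reference import Species, get_sequence, theoretical_ladder
from abquant.synthdata import SpectrumSimConfig


@pytest.fixture(scope="session")
def human_1_16():
    return get_sequence(Species.human, 1, 16)


@pytest.fixture(scope="session")
def ladder_1_16(human_1_16):
    return theoretical_ladder(human_1_16)


@pytest.fixture
def noiseless_config():
    """Deterministic spectrum generator: no intensity noise, jitter, or background."""
    return SpectrumSimConfig(
        noise_cv=0.0, n_background_peaks=0, mz_jitter_da=0.0
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
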