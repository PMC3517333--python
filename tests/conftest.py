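import numpy as np
import pytest

from paee.compendium import default_compendium
from paee.simulate import NoiseConfig, generate_cohort


@pytest.fixture(scope="session")
def comp():
    return default_compendium()


@pytest.fixture(scope="session")
def cohort20():
    return generate_cohort(20, seed=11)


@pytest.fixture(scope="session")
def participant(cohort20):
    return cohort20[0][0]


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def no_noise():
    return NoiseConfig.zero()
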