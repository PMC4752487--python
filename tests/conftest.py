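import numpy as np
import pytest

from countpower.distributions import CountFamily
from countpower.simulate import EffectSpec, solve_exposure_params


@pytest.fixture(scope="session")
def exposure():
    """The reference exposure distribution (solved once per session)."""
    return solve_exposure_params()


@pytest.fixture(scope="session")
def poisson_family():
    return CountFamily("poisson")


@pytest.fixture()
def rng():
    return np.random.default_rng(20160212)


@pytest.fixture()
def binary_effect():
    return EffectSpec("fixed_categorical", lambda0=0.02, strength=0.5)
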