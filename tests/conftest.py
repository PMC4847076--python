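import numpy as np
import pytest

from gelrct import Scenario, TrialData

SEED = 1234


@pytest.fixture
def rng():
    return np.random.default_rng(SEED)


@pytest.fixture
def normal_k1():
    """One normal-family trial, rho=0.5, one covariate, n=200."""
    return Scenario(dist="normal", rho=0.5, k=1, seed=SEED).sample()


@pytest.fixture
def normal_k2():
    return Scenario(dist="normal", rho=0.5, k=2, seed=SEED).sample()


@pytest.fixture
def normal_k0():
    return Scenario(dist="normal", rho=0.5, k=0, seed=SEED).sample()


@pytest.fixture
def toy4():
    """Tiny printed fixture: 4 observations, 1 covariate."""
    return TrialData(
        y=np.array([1.0, 2.0, 3.0, 5.0]),
        z=np.array([0, 0, 1, 1]),
        X=np.array([[0.5], [-0.5], [1.5], [0.5]]),
    )
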