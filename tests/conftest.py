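import numpy as np
import pytest

from nonmarkov.envs import build_switch_env
from nonmarkov.synth import CANONICAL_ENV_SEED, make_fixture


@pytest.fixture(scope="session")
def canonical_env():
    """The frozen reconstructed switch-state environment."""
    return build_switch_env(CANONICAL_ENV_SEED)


@pytest.fixture(scope="session")
def gated_chain():
    return make_fixture("gated-chain-3")


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
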