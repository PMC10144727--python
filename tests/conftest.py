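import numpy as np
import pytest

from emgdqn.synthetic import SynthConfig, default_profiles, generate_user


@pytest.fixture(scope="session")
def profiles():
    return default_profiles()


@pytest.fixture(scope="session")
def small_config():
    """Short recordings / small splits: fast but every stage exercised."""
    return SynthConfig(T=500, n_train=12, n_test=6, n_sync=2, seed=5)


@pytest.fixture(scope="session")
def small_user(profiles, small_config):
    return generate_user(profiles, small_config, user_id="small")


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
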