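import numpy as np
import pytest

from pigeonpop import build_stimulus_set, schedule_session


@pytest.fixture(scope="session")
def full_stimulus_set():
    return build_stimulus_set(seed=0)


@pytest.fixture(scope="session")
def full_schedule(full_stimulus_set):
    return schedule_session(full_stimulus_set, seed=1)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
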