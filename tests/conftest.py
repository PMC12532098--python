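import numpy as np
import pytest

from mocorr import PRESETS, PhantomSpec, build_schedule, corrupt, make_phantom


@pytest.fixture(scope="session")
def sched_default():
    return build_schedule()


@pytest.fixture(scope="session")
def phantom64():
    return make_phantom(PhantomSpec(size=64, seed=3))


@pytest.fixture(scope="session")
def heavy_pair(phantom64):
    return corrupt(phantom64, PRESETS["heavy"], rng_seed=1)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
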