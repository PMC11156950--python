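import numpy as np
import pytest

import fcga


@pytest.fixture(scope="session")
def cortex10():
    return fcga.make_toy_cortex(10, 10)


@pytest.fixture(scope="session")
def small_ground_truth(cortex10):
    return fcga.make_ground_truth(cortex10, m=3, seed=11)


@pytest.fixture(scope="session")
def small_timeseries(small_ground_truth):
    return fcga.simulate_timeseries(small_ground_truth, T=60, seed=21)


@pytest.fixture(scope="session")
def small_gradients(small_timeseries):
    return fcga.full_gradients(small_timeseries, n_components=5, zero_variance="zero")


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
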