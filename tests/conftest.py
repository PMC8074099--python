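import logging

import numpy as np
import pytest

import dorsalhorn as dh


@pytest.fixture(autouse=True)
def _quiet_spike_warnings(caplog):
    # late C-fiber background spikes delayed past the simulation end are
    # dropped with a warning on every realization; keep test output readable
    logging.getLogger("dorsalhorn.spike_trains").setLevel(logging.ERROR)
    yield


@pytest.fixture(scope="session")
def default_params() -> dh.DHParameters:
    return dh.DHParameters.default()


@pytest.fixture(scope="session")
def base_config() -> dh.ExperimentConfig:
    return dh.ExperimentConfig(master_seed=1)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


def random_small_train(rng: np.random.Generator, max_spikes: int = 12) -> dh.SpikeTrain:
    """A short strictly-increasing random spike train for oracle comparisons."""
    n = int(rng.integers(0, max_spikes + 1))
    if n == 0:
        return dh.SpikeTrain(np.empty(0))
    t = np.sort(rng.uniform(0.0, 100.0, size=n))
    t = t[np.concatenate(([True], np.diff(t) > 1e-9))]
    return dh.SpikeTrain(t)
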