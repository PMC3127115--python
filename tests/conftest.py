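import numpy as np
import pytest

from ynobde import dataset, simdata


@pytest.fixture(scope="session")
def fixture_table():
    return dataset.load_fixture()


@pytest.fixture(scope="session")
def reported_deviations():
    return dataset.load_reported_deviations()


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)


@pytest.fixture
def small_sim_table():
    spec = simdata.SimSpec(
        n_molecules=60, n_relevant=3, n_noise=4, correlation=0.5, seed=7
    )
    return simdata.generate(spec)
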