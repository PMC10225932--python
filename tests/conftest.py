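import numpy as np
import pytest

from mtcnkit import simulate


@pytest.fixture(scope="session")
def cohort_config():
    return simulate.SimulationConfig(n_individuals=600, seed=11)


@pytest.fixture(scope="session")
def cohort(cohort_config):
    return simulate.simulate_cohort(cohort_config)


@pytest.fixture(scope="session")
def marker_map():
    return simulate.uniform_marker_map(n_chromosomes=2, markers_per_chromosome=80)


@pytest.fixture(scope="session")
def local_ancestry(cohort, marker_map, cohort_config):
    return simulate.simulate_local_ancestry(cohort, marker_map, cohort_config, seed=21)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
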