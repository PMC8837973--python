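import numpy as np
import pytest

from cholinetrace.core_io import default_registry, reference_pools
from cholinetrace.simulator import (SimulationConfig, default_network,
                                    sample_study, simulate)


@pytest.fixture(scope="session")
def registry():
    return default_registry()


@pytest.fixture(scope="session")
def reference():
    return reference_pools()


@pytest.fixture(scope="session")
def network():
    return default_network()


@pytest.fixture(scope="session")
def trajectories(network):
    """Deterministic unit-dose trajectories at the study time points."""
    return simulate(network, 1.0, [1.5, 6.0, 24.0])


@pytest.fixture(scope="session")
def small_study(network, trajectories):
    """One small noiseless synthetic study (3 animals per time point)."""
    config = SimulationConfig(n_animals_per_timepoint=3, animal_cv=0.0,
                              technical_cv=0.0, seed=11)
    return config, sample_study(network, config, trajectories=trajectories)


@pytest.fixture
def rng():
    return np.random.default_rng(20220720)
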