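import dataclasses

import numpy as np
import pytest

from cobedis.parcellation import make_lookup
from cobedis.simulate import SimulationConfig


@pytest.fixture(scope="session")
def lookup100():
    return make_lookup(100)


@pytest.fixture(scope="session")
def lookup40():
    return make_lookup(40)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def fast_sim_config():
    """Small, quick generator config used by pipeline-level tests."""
    return SimulationConfig(
        n_regions=40,
        n_subjects=18,
        subgroup_size=4,
        n_timepoints=80,
        k_individual=3,
        seed=7,
    )


def null_battery(config: SimulationConfig):
    """Copy of a config's battery with every group effect removed."""
    return tuple(
        dataclasses.replace(m, mean_subgroup=m.mean_majority) for m in config.battery
    )
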