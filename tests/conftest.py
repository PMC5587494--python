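import numpy as np
import pandas as pd
import pytest

from warblerstop.config import SimulationConfig


@pytest.fixture
def config():
    """Default simulation configuration with a fixed seed."""
    return SimulationConfig(seed=42)


@pytest.fixture
def small_config():
    """Small study for fast end-to-end smoke tests."""
    return SimulationConfig(seed=42, n_birds_per_group=30, n_plasma=40)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def regions():
    return {"southeast": (-50.0, -10.0), "boreal": (-130.0, -70.0)}


@pytest.fixture
def plasma_birds(config):
    """A generated bird table with truth columns renamed for modeling."""
    from warblerstop.synth import gen_birds, gen_metabolite_samples

    birds = gen_birds(config)
    plasma = gen_metabolite_samples(config, birds)
    birds = birds.rename(
        columns={
            "true_destination": "destination",
            "true_timing": "timing",
            "true_condition": "condition",
        }
    )
    return plasma, birds
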