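import numpy as np
import pytest

from objspace.memory_model import ModelParams
from objspace.schedule import generate_session
from objspace.synthetic_data import CohortSpec, generate_dataset


@pytest.fixture(scope="session")
def rat_overlapping():
    return generate_session("overlapping", "rat_2day", counterbalance_slot=0, seed=1)


@pytest.fixture(scope="session")
def rat_stable():
    return generate_session("stable", "rat_2day", counterbalance_slot=0, seed=1)


@pytest.fixture(scope="session")
def m1_params():
    return ModelParams("M1", alpha=0.6, beta=0.2)


@pytest.fixture(scope="session")
def small_rat_dataset():
    """Small rat cohort with strongly neophilic agents (all 3 conditions)."""
    spec = CohortSpec(n_animals=4, protocol="rat_2day", seed=42)
    return generate_dataset(spec)
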