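"""Shared fixtures: published-truth parameters and small simulated datasets."""

import numpy as np
import pytest

from jointlsm.core import JointParams, SubjectEffects
from jointlsm.simulate import make_scenario, simulate


@pytest.fixture(scope="session")
def table1_params() -> JointParams:
    """Linear truth of the main simulation scenario."""
    return make_scenario("table1").params


@pytest.fixture(scope="session")
def small_dataset():
    """A 60-subject dataset from the linear scenario (fast fits)."""
    return simulate(make_scenario("table1", n_subjects=60, seed=314))


@pytest.fixture(scope="session")
def medium_dataset():
    """A 300-subject dataset from the linear scenario."""
    return simulate(make_scenario("table1", n_subjects=300, seed=2718))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def nonzero_effects():
    return SubjectEffects(u1=2.0, u2=0.5)
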