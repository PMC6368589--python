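import numpy as np
import pytest
from hypothesis import settings

from spinecoupling import SynthConfig, generate_population
from spinecoupling.records import split_by_condition

settings.register_profile("ci", derandomize=True, deadline=None, max_examples=25)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_population():
    """Population drawn under the default generator configuration."""
    return generate_population(SynthConfig())


@pytest.fixture(scope="session")
def default_groups(default_population):
    control, cltp = split_by_condition(default_population)
    return control, cltp


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
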