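import numpy as np
import pytest

from pswsim import dgp


@pytest.fixture(scope="session")
def pop_small() -> dgp.SuperPopulation:
    """Moderate-size calibrated population shared across unit tests."""
    return dgp.build_super_population(50_000, 0.5, seed=123)


@pytest.fixture(scope="session")
def sample_1000(pop_small) -> dgp.Sample:
    return dgp.draw_sample(pop_small, 1000, np.random.default_rng(7))
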