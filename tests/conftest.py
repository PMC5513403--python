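import numpy as np
import pytest

import adpkdval as av


@pytest.fixture(scope="session")
def truth():
    return av.default_truth()


@pytest.fixture(scope="session")
def small_cohort():
    """A modest realistic cohort shared across read-only tests."""
    return av.generate_cohort(av.GeneratorConfig(n_patients=80, seed=11))


@pytest.fixture(scope="session")
def noiseless_cohort():
    return av.generate_cohort(av.noiseless_config(40, seed=5))


@pytest.fixture()
def rng():
    return np.random.default_rng(202409)
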