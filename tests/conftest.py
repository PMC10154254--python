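import numpy as np
import pytest

from ssns_grs import build_default_model, emulate_paper_cohorts


@pytest.fixture(scope="session")
def model():
    return build_default_model()


@pytest.fixture(scope="session")
def bundle():
    """One full-size synthetic study, shared across tests."""
    return emulate_paper_cohorts(seed=20240317)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
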