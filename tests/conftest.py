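import numpy as np
import pytest
from hypothesis import settings

import aarsloc as a

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def inventory():
    return a.load_packaged_inventory()


@pytest.fixture(scope="session")
def gt_profile():
    return a.load_packaged_profile("Guillardia theta")


@pytest.fixture(scope="session")
def pt_profile():
    return a.load_packaged_profile("Phaeodactylum tricornutum")


@pytest.fixture(scope="session")
def tp_profile():
    return a.load_packaged_profile("Thalassiosira pseudonana")


@pytest.fixture
def rng():
    return np.random.default_rng(20150520)
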