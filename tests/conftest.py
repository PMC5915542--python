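import numpy as np
import pytest

from adtfnet import HeadModel, Montage, SUBSET_19, build_lead_field
from adtfnet.io import MONTAGE_64


@pytest.fixture(scope="session")
def montage19():
    return Montage.standard(SUBSET_19)


@pytest.fixture(scope="session")
def montage64():
    return Montage.standard(MONTAGE_64)


@pytest.fixture(scope="session")
def head():
    return HeadModel()


@pytest.fixture(scope="session")
def lead_field19(montage19, head):
    return build_lead_field(montage19, head, n_sources=800)


@pytest.fixture(scope="session")
def lead_field64(montage64, head):
    return build_lead_field(montage64, head, n_sources=1500)


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)
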