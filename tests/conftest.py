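import pytest

from cavenit.config import Constants
from cavenit.samples import FractionationSet


@pytest.fixture
def constants():
    return Constants()


@pytest.fixture
def no_temp_correction():
    """Constants with both van't Hoff corrections disabled."""
    return Constants(dH_dissoc_kJ_mol=0.0, kh_vant_hoff_K=0.0)


@pytest.fixture
def chain_defaults():
    return FractionationSet()
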