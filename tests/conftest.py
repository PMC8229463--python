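import pytest

from fexupk.clearance import build_clu_int
from fexupk.model_config import default_drug_parameters, default_physiology


@pytest.fixture(scope="session")
def phys():
    return default_physiology()


@pytest.fixture(scope="session")
def drug():
    return default_drug_parameters()


@pytest.fixture(scope="session")
def clearance_model(drug):
    return build_clu_int(drug)
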