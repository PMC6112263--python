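import pytest

from afecon import CostParameters, ModelParameters, DEFAULT_RISK_TABLE


@pytest.fixture(scope="session")
def params() -> ModelParameters:
    return ModelParameters()


@pytest.fixture(scope="session")
def costs() -> CostParameters:
    return CostParameters()


@pytest.fixture(scope="session")
def risk_table():
    return DEFAULT_RISK_TABLE
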