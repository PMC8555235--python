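import pytest

from transoral_cua import CostUtilityModel, load_default_parameters


@pytest.fixture(scope="session")
def params():
    return load_default_parameters()


@pytest.fixture(scope="session")
def model():
    """Base-case model with the frozen default life table and salvage config."""
    return CostUtilityModel()


@pytest.fixture(scope="session")
def base_results(model):
    return model.evaluate()
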