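import pytest

from glycoprofiler import simulate


@pytest.fixture(scope="session")
def default_model():
    return simulate.default_ncg_model()


@pytest.fixture(scope="session")
def zero_noise_model():
    return simulate.default_ncg_model().zero_noise()


@pytest.fixture(scope="session")
def ncg(default_model):
    return default_model.proteins[0]
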