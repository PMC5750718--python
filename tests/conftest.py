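import pytest

from vispop import default_config, default_models


@pytest.fixture(scope="session")
def models():
    return default_models()


@pytest.fixture()
def config():
    return default_config()
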