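import pytest
from hypothesis import settings

from tandemcnv.repeat_model import default_architecture

settings.register_profile("default", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("default")


@pytest.fixture(scope="session")
def arch():
    return default_architecture()
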