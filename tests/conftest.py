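import pytest

from salem.params import load_default_parameters


@pytest.fixture(scope="session")
def registry():
    return load_default_parameters()
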