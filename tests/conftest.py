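import pytest

from equiasym import load_scales


@pytest.fixture(scope="session")
def scales():
    return load_scales()
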