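import pytest

from hydroscan.align import default_params
from hydroscan.panel import default_panel


@pytest.fixture(scope="session")
def panel():
    return default_panel()


@pytest.fixture(scope="session")
def params():
    return default_params()
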