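import pytest

from ccmort.registry import load_fixture


@pytest.fixture(scope="session")
def table2():
    """Packaged monthly death-count series per study period."""
    return load_fixture("table2")


@pytest.fixture(scope="session")
def table1():
    return load_fixture("table1")
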