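import pytest

from ctshield import load_fixture


@pytest.fixture(scope="session")
def paper_fixture():
    return load_fixture()
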