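import pytest

import carotannot as ca


@pytest.fixture(scope="session")
def db():
    return ca.load_reference()


@pytest.fixture()
def fixture_ds():
    return ca.table1_fixture()
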