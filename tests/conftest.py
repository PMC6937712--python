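import pytest

from sealcua import base_case_fixture


@pytest.fixture(scope="session")
def base_fixture():
    return base_case_fixture()
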