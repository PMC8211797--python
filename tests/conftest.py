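import pytest

from bescan import fixtures
from bescan.design_scan import get_profile


@pytest.fixture(scope="session")
def mdx4cv():
    return fixtures.build_mdx4cv_fixture()


@pytest.fixture(scope="session")
def ng_profile():
    return get_profile("NG")


@pytest.fixture(scope="session")
def ngg_profile():
    return get_profile("NGG")
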