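import pytest

from crisprdual import ScreenDesign, fixtures


@pytest.fixture(scope="session")
def invivo_lib():
    return fixtures.invivo_library()


@pytest.fixture(scope="session")
def invitro_lib():
    return fixtures.invitro_library()


@pytest.fixture(scope="session")
def invitro_design():
    return ScreenDesign.in_vitro()


@pytest.fixture(scope="session")
def invivo_design():
    return ScreenDesign.in_vivo()
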