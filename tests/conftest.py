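import pytest

from nanonuc import eos, interfaces


@pytest.fixture(scope="session")
def pfp():
    return eos.FluidProperties.pfp()


@pytest.fixture()
def droplet():
    return interfaces.DropletConfig()


@pytest.fixture()
def tissue():
    return interfaces.TissueConfig()


@pytest.fixture(scope="session")
def pspin_310(pfp):
    _, psp = eos.liquid_spinodal(310.0, pfp)
    return psp
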