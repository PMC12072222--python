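import pytest

from cpipbpk import core
from cpipbpk.io import load_builtin_inhibitor
from cpipbpk.params import PhysiologyRef, cp1_reference


@pytest.fixture(scope="session")
def phys():
    return PhysiologyRef.reference(70.0)


@pytest.fixture(scope="session")
def cp1(phys):
    """CP-I calibrated to a 10 % renal elimination fraction (default target)."""
    gamma = core.calibrate_hepatic_scaler(cp1_reference(), phys, {"fe": 0.10})
    return cp1_reference(gamma)


@pytest.fixture(scope="session")
def cp1_css(phys):
    """CP-I calibrated so the reference baseline equals the 0.685 nM
    literature mean."""
    gamma = core.calibrate_hepatic_scaler(cp1_reference(), phys, {"css": 0.685})
    return cp1_reference(gamma)


@pytest.fixture(scope="session")
def rifampicin_like():
    return load_builtin_inhibitor("rifampicin_like")


@pytest.fixture(scope="session")
def probenecid_like():
    return load_builtin_inhibitor("probenecid_like")
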