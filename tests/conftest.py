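import numpy as np
import pytest

from cmquant.presets import (APTargets, GatingPreset, InactProtocol,
                             StriationGeometry, TransientTargets,
                             VClampProtocol, donor_preset, r1267q_preset,
                             v2264m_preset)


@pytest.fixture(scope="session")
def donor() -> GatingPreset:
    return donor_preset()


@pytest.fixture(scope="session")
def r1267q() -> GatingPreset:
    return r1267q_preset()


@pytest.fixture(scope="session")
def v2264m() -> GatingPreset:
    return v2264m_preset()


@pytest.fixture(scope="session")
def vclamp_protocol() -> VClampProtocol:
    return VClampProtocol()


@pytest.fixture(scope="session")
def inact_protocol() -> InactProtocol:
    return InactProtocol()


@pytest.fixture(scope="session")
def ap_targets() -> APTargets:
    return APTargets()


@pytest.fixture(scope="session")
def transient_targets() -> TransientTargets:
    return TransientTargets()


@pytest.fixture(scope="session")
def striation_geometry() -> StriationGeometry:
    return StriationGeometry()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
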