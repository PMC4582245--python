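import numpy as np
import pytest

from ssbwrap.geometry import ConstraintEnvelope
from ssbwrap.landscape import EnergyLandscape
from ssbwrap.polymer import PolymerParams
from ssbwrap.simulate import fixture_wrapping_path


@pytest.fixture(scope="session")
def params() -> PolymerParams:
    return PolymerParams()


@pytest.fixture(scope="session")
def landscape() -> EnergyLandscape:
    return EnergyLandscape.reference()


@pytest.fixture(scope="session")
def fixture_structure():
    return fixture_wrapping_path(70)


@pytest.fixture(scope="session")
def fixture_envelope(fixture_structure) -> ConstraintEnvelope:
    return ConstraintEnvelope.from_structure(fixture_structure)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20260920)
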