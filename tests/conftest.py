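import numpy as np
import pytest

from mdoe_carrier.kinetic_model import CarrierSpec, CultureSetup, KineticParameters
from mdoe_carrier.synthetic_data import DEFAULT_CARRIER, GroundTruth, generate_modeling_set


@pytest.fixture(scope="session")
def carrier() -> CarrierSpec:
    return DEFAULT_CARRIER


@pytest.fixture(scope="session")
def params() -> KineticParameters:
    return KineticParameters()


@pytest.fixture(scope="session")
def setup(carrier) -> CultureSetup:
    return CultureSetup(carrier=carrier, c_MC=1.0, seed_density=6000.0, c_Glc=25.0, c_Gln=4.0)


@pytest.fixture(scope="session")
def t_grid() -> np.ndarray:
    return np.arange(0.0, 264.0 + 1e-9, 4.0)


@pytest.fixture(scope="session")
def truth() -> GroundTruth:
    return GroundTruth()


@pytest.fixture(scope="session")
def clean_truth() -> GroundTruth:
    """Effectively noise-free ground truth for round-trip fits."""
    return GroundTruth(noise=1e-9)


@pytest.fixture(scope="session")
def clean_modeling_set(clean_truth):
    return generate_modeling_set(clean_truth, seed=11)
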