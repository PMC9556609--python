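import numpy as np
import pytest

from demix import AttenuationVector, BasisMaterial, BasisSet, EnergyPair
from demix import materials


@pytest.fixture
def aqueous_triplet() -> BasisSet:
    """Iomeprol / eosin / NaCl with regression-endpoint attenuations."""
    return BasisSet(
        (materials.iomeprol(), materials.eosin(), materials.sodium_chloride()),
        EnergyPair(50, 200),
    )


@pytest.fixture
def clot_basis() -> BasisSet:
    return materials.clot_basis()


@pytest.fixture
def formalin() -> BasisMaterial:
    return materials.formalin()


@pytest.fixture
def iomeprol() -> BasisMaterial:
    return materials.iomeprol()


@pytest.fixture
def water() -> AttenuationVector:
    return materials.WATER_ATTENUATION


def random_simplex(rng: np.random.Generator, n: int) -> np.ndarray:
    return rng.dirichlet(np.ones(n))
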