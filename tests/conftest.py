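import numpy as np
import pytest

from bonerad import BONE, penetration_depths, penetration_distribution
from bonerad.materials import photoelectron_energy

#: Ca K photoelectron energy for the 18 keV beam, used throughout.
E_PHOTOELECTRON = photoelectron_energy(18.0, "Ca", "K")


@pytest.fixture(scope="session")
def bone_depths():
    """Medium Monte-Carlo run shared by transport and acceptance tests."""
    return penetration_depths(E_PHOTOELECTRON, BONE, n=10000, seed=20260901)


@pytest.fixture(scope="session")
def bone_pdist(bone_depths):
    return penetration_distribution(
        bone_depths, n_bins=120, material="bone", energy_kev=E_PHOTOELECTRON,
        seed=20260901,
    )


@pytest.fixture(scope="session")
def small_depths():
    """Cheap run for qualitative checks."""
    return penetration_depths(E_PHOTOELECTRON, BONE, n=1500, seed=7)
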