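import numpy as np
import pytest

import beadvol as bv
from beadvol.experiment import PhantomSpec

#: measured reference densities of the physical phantom materials
TRUE_MATERIALS = bv.MaterialPair(hu_object=119.9, hu_background=-149.7)

#: a small phantom shared by the slower end-to-end tests
SMALL_SPEC = PhantomSpec(count_target=60, container=(30.0, 30.0, 24.0),
                         margin_mm=12.0)


@pytest.fixture(scope="session")
def true_materials():
    return TRUE_MATERIALS


@pytest.fixture(scope="session")
def small_sim():
    """One noise-free voxelized phantom replicate (60-bead scale)."""
    return bv.simulate_phantom(seed=11, spec=SMALL_SPEC)


@pytest.fixture()
def uniform_volume():
    """A 4-slice uniform background volume at 0.5 mm pixels."""
    hu = np.full((4, 40, 40), -149.7)
    return bv.CTVolume(hu=hu, spacing=(0.5, 0.5, 1.0))
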