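import numpy as np
import pytest

import pbilung as P
from pbilung.phantom import PhantomSpec, make_chest_phantom, make_cylinder_phantom


@pytest.fixture(scope="session")
def small_spec():
    return PhantomSpec(
        nx=128, ny=128, nz=16, voxel_size=0.4,
        thorax_rx=23.0, thorax_ry=18.0, lung_offset_x=10.0,
        lung_rx=7.5, lung_ry=10.5, rib_radius=1.2,
        seed=3,
    )


@pytest.fixture(scope="session")
def chest(small_spec):
    return make_chest_phantom(small_spec)


@pytest.fixture(scope="session")
def soft_cylinder():
    """Soft-tissue cylinder, 10 mm radius, in air; analytic oracle phantom."""
    return make_cylinder_phantom(10.0, P.SOFT_TISSUE, grid=(4, 128, 128), voxel_size=0.25)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
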