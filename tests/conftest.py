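import numpy as np
import pytest
import trimesh

from augvol import validate_mesh
from augvol.phantom import PhantomSpec, generate_phantom


@pytest.fixture
def unit_cube():
    return validate_mesh(trimesh.creation.box((1.0, 1.0, 1.0)))


@pytest.fixture
def icosphere():
    """Radius-5 mm icosphere, fine enough for sub-0.5 % volume agreement."""
    return validate_mesh(trimesh.creation.icosphere(subdivisions=4, radius=5.0))


@pytest.fixture(scope="session")
def block_phantom():
    """One noiseless block-augmentation phantom pair (shared, read-only)."""
    return generate_phantom(PhantomSpec(technique="B", seed=11))


@pytest.fixture(scope="session")
def coarse_spec():
    """Coarser tessellation for registration tests that do not need volumes."""
    return PhantomSpec(seed=11, grid_step=0.4)
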