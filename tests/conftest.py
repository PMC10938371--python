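import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make tests/oracles.py importable

from biofilmvoxel import BinaryMask, VoxelGrid

STAINING_SPACING = (0.5, 404.63 / 1430, 404.63 / 1430)
FISH_SPACING = (0.5, 202.83 / 1024, 202.83 / 1024)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def random_mask(rng):
    """A moderately dense random mask on an isotropic 1 μm lattice."""
    return BinaryMask(rng.random((10, 12, 12)) < 0.3, (1.0, 1.0, 1.0), "Pa")


@pytest.fixture
def random_grid(rng):
    values = rng.integers(0, 256, size=(6, 16, 16)).astype(float)
    return VoxelGrid(values, (0.5, 0.2, 0.2), "Pa")
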