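import numpy as np
import pytest

from neurofuse.volumes import ComponentStack, Volume, VolumeGrid


@pytest.fixture
def grid():
    return VolumeGrid.isotropic((8, 8, 8), 3.0)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def random_volume(grid, rng):
    return Volume(grid, rng.normal(size=grid.dims))


@pytest.fixture
def random_stack(grid, rng):
    return ComponentStack.from_array(grid, rng.normal(size=(5,) + grid.dims))


@pytest.fixture
def positive_volume(grid, rng):
    return Volume(grid, rng.uniform(0.1, 1.0, size=grid.dims))
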