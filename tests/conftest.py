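import numpy as np
import pytest

from dcslet.scoring import ScoreMaps, VoxelGrid


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_grid():
    """4 x 4 x 4 voxels of 1 cm: coarse enough to hand-check traversals."""
    return VoxelGrid(origin=(0.0, 0.0, 0.0), spacing=(1.0, 1.0, 1.0),
                     dims=(4, 4, 4))


@pytest.fixture
def small_maps(small_grid):
    return ScoreMaps(small_grid)


@pytest.fixture(scope="session")
def beamlet_90():
    """One shared 90 MeV uncollimated beamlet run (20k histories)."""
    from dcslet.transport import simulate_beamlet
    return simulate_beamlet(90.0, n=20_000, seed=7)
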