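import numpy as np
import pytest

from bmrisk import RegionSpec, SyntheticScenario, Volume3D, make_atlas


@pytest.fixture
def identity_grid():
    """Factory for 1 mm isotropic grids with an identity voxel-to-world map."""

    def _make(shape=(32, 32, 32), dtype=np.int16):
        return Volume3D(data=np.zeros(shape, dtype=dtype), voxel_to_world=np.eye(4))

    return _make


@pytest.fixture
def two_box_atlas():
    """Two disjoint 1 mm box regions: A (20^3 = 8000 mm3), B (10^3 = 1000 mm3)."""
    scenario = SyntheticScenario(
        grid_shape=(48, 48, 48),
        voxel_size_mm=1.0,
        regions=[
            RegionSpec("boxA", "A", "box", (11.5, 11.5, 11.5), (20, 20, 20)),
            RegionSpec("boxB", "B", "box", (35.5, 35.5, 35.5), (10, 10, 10)),
        ],
    )
    return make_atlas(scenario)
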