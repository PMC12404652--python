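import numpy as np
import pytest

from endopheno import RegionSet, SceneSpec, simulate_field


@pytest.fixture(scope="session")
def noisefree_scene():
    """A small noise-free field with moderate punctate signal."""
    spec = SceneSpec(n_cells=6, punctate_fraction=0.5, photon_noise=False,
                     read_sigma=0.0, field_shape=(256, 256), seed=42)
    return simulate_field(spec)


@pytest.fixture
def single_cell_regions():
    """Factory: a RegionSet whose single cell covers given coordinates."""

    def make(shape=(16, 16), coords=None):
        mask = np.zeros(shape, dtype=np.int32)
        if coords is None:
            mask[2:14, 2:14] = 1
        else:
            mask[tuple(np.array(coords).T)] = 1
        return RegionSet(label_mask=mask)

    return make
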