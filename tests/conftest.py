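import numpy as np
import pytest

from oculobrain import synthetic
from oculobrain.fmri import VoxelTimeSeriesVolume


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_volume(rng):
    """A tiny 4-D noise volume (6x6x4, 60 frames, TR 2 s)."""
    data = rng.normal(size=(6, 6, 4, 60))
    return VoxelTimeSeriesVolume(data=data, affine=np.diag([3.0, 3.0, 3.0, 1.0]), tr=2.0)


@pytest.fixture
def tiny_cohort_config():
    """A fast cohort config: 6+6 subjects on an 8x8x6 grid, 60 volumes."""
    cfg = synthetic.CohortConfig(seed=7)
    cfg.group_sizes = {"HC": 6, "SCD": 2, "MCI": 6, "AD": 2}
    cfg.grid = synthetic.GridSpec(shape=(8, 8, 6), n_volumes=60)
    cfg.retina = synthetic.RetinaSpec(image_size=128, pixel_size_mm=3.0 / 128)
    eff = synthetic.default_planted_effect()
    eff.blob_center = (4, 4, 3)
    eff.blob_radius_vox = 1.2
    cfg.effects = [eff]
    return cfg
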