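import numpy as np
import pytest

from gliamorph.config import PipelineConfig
from gliamorph.image_io import VoxelGrid


@pytest.fixture
def iso_config() -> PipelineConfig:
    """Isotropic 0.5 µm voxels: the standard phantom geometry."""
    return PipelineConfig(spacing=(0.5, 0.5, 0.5))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20250930)


def make_grid(data: np.ndarray, spacing=(0.5, 0.5, 0.5)) -> VoxelGrid:
    return VoxelGrid(data=data, spacing=spacing, source_id="test")


@pytest.fixture
def two_level_stack() -> VoxelGrid:
    """Half the voxels 0, half 10: Otsu tie-break forcing case."""
    data = np.zeros((4, 4, 4), dtype=np.uint8)
    data[:2] = 10
    return make_grid(data)
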