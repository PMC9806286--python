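import numpy as np
import pytest

from spleenvol.phantoms import PhantomSpec, VoxelizationConfig, voxelize


@pytest.fixture(scope="session")
def sphere_phantom():
    """A 3 cm sphere voxelized at 1 mm in-plane, 5 mm contiguous slices."""
    spec = PhantomSpec(semi_axes=(3.0, 3.0, 3.0))
    cfg = VoxelizationConfig(
        pixel_spacing=(0.1, 0.1), slice_thickness=0.5, slice_gap=0.0, slice_offset=0.0
    )
    series, mask, truth = voxelize(spec, cfg)
    return spec, cfg, series, mask, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(20160901)
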