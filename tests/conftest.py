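import numpy as np
import pytest

from pcls4d.synthetic import SimConfig, SolutionProtocol, TransportParams


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_config():
    """A slab small enough for fast unit tests (few cells)."""
    return SimConfig(shape=(12, 40, 40), voxel_size=(10.0, 2.0, 2.0),
                     slab_thickness=100.0, packing_fraction=0.35, seed=7)


@pytest.fixture
def column_config():
    """Cells-free 1D column of the standard slab geometry."""
    return SimConfig(shape=(40, 3, 3), voxel_size=(10.0, 64.0, 64.0),
                     slab_thickness=300.0, packing_fraction=0.0)


@pytest.fixture
def step_protocol():
    return SolutionProtocol(baseline_mosm=300.0, switches=((0.0, 600.0, 0.0),),
                            duration=120.0, frame_interval=15.0)


@pytest.fixture
def default_params():
    return TransportParams()
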