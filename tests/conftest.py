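import numpy as np
import pytest

from voroclust import Box, simulate_uniform


@pytest.fixture
def unit_box_3d():
    return Box([0.0, 0.0, 0.0], [1000.0, 1000.0, 1000.0])


@pytest.fixture
def uniform_300(unit_box_3d):
    """Small 3D uniform cloud reused across geometric tests."""
    return simulate_uniform(300, unit_box_3d, seed=4)


@pytest.fixture
def grid_3x3x3():
    """27-point axis-aligned grid, spacing 1; center point has index 13."""
    axes = np.arange(3.0)
    pts = np.stack(np.meshgrid(axes, axes, axes, indexing="ij"), -1).reshape(-1, 3)
    return pts
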