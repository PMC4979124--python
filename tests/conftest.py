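import numpy as np
import pytest

from hyphamorph import (
    CellSegment,
    HyphalSkeleton,
    ImageStack,
    SeptumNode,
    VoxelGrid,
)
from hyphamorph.core import PAPER_DX_UM


@pytest.fixture
def small_grid():
    return VoxelGrid(nx=16, ny=16, nz=8, dx=0.5, dy=0.5, dz=1.0)


@pytest.fixture
def crop_grid():
    """A paper-spacing crop large enough for a ~12 µm tube."""
    return VoxelGrid(nx=96, ny=96, nz=32, dx=PAPER_DX_UM, dy=PAPER_DX_UM, dz=0.46)


@pytest.fixture
def simple_skeleton(small_grid):
    nodes = [
        SeptumNode(id="a", x=1.0, y=1.0, z=1.0),
        SeptumNode(id="b", x=9.0, y=1.0, z=1.0),
    ]
    cells = [CellSegment(id="c1", node_a="a", node_b="b")]
    return HyphalSkeleton(grid=small_grid, nodes=nodes, cells=cells)


@pytest.fixture
def flat_stack(small_grid):
    return ImageStack(
        intensities=np.full(small_grid.shape, 7.0, dtype=float), grid=small_grid
    )


@pytest.fixture(scope="session")
def table1_records():
    from hyphamorph import load_table1_fixture

    return load_table1_fixture()
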