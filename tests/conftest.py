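import numpy as np
import pytest

from mvds.fields import FieldMaps, VoxelGrid, t2_field
from mvds.network import VascularNetwork, VesselEdge, VesselNode, VesselType


@pytest.fixture
def empty_maps():
    """Vessel-free domain: uniform tissue, zero ΔB, B0 = 3 T."""
    grid = VoxelGrid((50, 50, 50), 2.0)
    lum = np.zeros(grid.shape, dtype=bool)
    maps = FieldMaps(
        grid, lum, np.full(grid.shape, -1), np.zeros(grid.shape), np.zeros(grid.shape + (3,))
    )
    maps.t2 = t2_field(lum, np.zeros(grid.shape), 3.0)
    maps.delta_b = np.zeros(grid.shape)
    return maps


@pytest.fixture
def single_tube():
    """One straight capillary along x with full physiology populated."""
    return VascularNetwork(
        nodes=[VesselNode(0, (10.0, 50.0, 50.0), 3.0), VesselNode(1, (190.0, 50.0, 50.0), 3.0)],
        edges=[
            VesselEdge(
                (0, 1),
                vessel_type=VesselType.CAPILLARY,
                flow_direction=1,
                speed=1.0,
                po2=60.0,
                so2=0.7,
                hematocrit=0.33,
            )
        ],
        bounding_box=(200.0, 100.0, 100.0),
    ).validate()


@pytest.fixture
def toy_network():
    """Two nodes, one 100 µm edge along x."""
    return VascularNetwork(
        nodes=[VesselNode(0, (0.0, 0.0, 0.0), 2.0), VesselNode(1, (100.0, 0.0, 0.0), 2.0)],
        edges=[VesselEdge((0, 1))],
        bounding_box=(100.0, 50.0, 50.0),
    ).validate()
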