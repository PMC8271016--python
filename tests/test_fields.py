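"""Rasterization, susceptibility, dipole field and T2 maps."""

import numpy as np
import pytest

from mvds.fields import (
    VoxelGrid,
    dipole_convolve,
    hematocrit_map,
    rasterize_network,
    susceptibility_map,
    t2_field,
    t2_tissue,
)
from mvds.network import ValidationError, VascularNetwork, VesselEdge, VesselNode, VesselType


def _cylinder_net(radius=4.0, length=100.0, box=(120.0, 40.0, 40.0)):
    return VascularNetwork(
        nodes=[
            VesselNode(0, (10.0, 20.0, 20.0), radius),
            VesselNode(1, (10.0 + length, 20.0, 20.0), radius),
        ],
        edges=[VesselEdge((0, 1), vessel_type=VesselType.CAPILLARY, speed=1.0, so2=0.6, hematocrit=0.33)],
        bounding_box=box,
    )


def test_cylinder_voxel_count_matches_analytic_volume():
    net = _cylinder_net()
    grid = VoxelGrid.for_box(net.bounding_box, 1.0)
    maps = rasterize_network(net, grid)
    analytic = np.pi * 4.0**2 * 100.0
    assert maps.lumen_mask.sum() == pytest.approx(analytic, rel=0.10)


def test_rasterization_converges_with_spacing():
    # segments rasterize as capsules (spherical end caps join smoothly at nodes)
    capsule = np.pi * 4.0**2 * 100.0 + 4.0 / 3.0 * np.pi * 4.0**3
    net = _cylinder_net()
    errs = []
    for h in (1.0, 0.25):
        maps = rasterize_network(net, VoxelGrid.for_box(net.bounding_box, h))
        errs.append(abs(maps.lumen_mask.sum() * h**3 - capsule) / capsule)
    assert errs[1] < errs[0]
    assert errs[1] < 0.02


def test_empty_network_all_tissue():
    net = VascularNetwork(nodes=[], edges=[], bounding_box=(20.0, 20.0, 20.0))
    maps = rasterize_network(net, VoxelGrid((10, 10, 10), 2.0))
    assert not maps.lumen_mask.any()
    assert np.all(maps.velocity == 0.0)


def test_velocity_zero_outside_lumen_and_plug_inside():
    net = _cylinder_net()
    maps = rasterize_network(net, VoxelGrid.for_box(net.bounding_box, 1.0))
    assert np.all(maps.velocity[~maps.lumen_mask] == 0.0)
    v = maps.velocity[maps.lumen_mask]
    assert np.allclose(v, [1.0, 0.0, 0.0])  # speed 1 mm/s = 1 µm/ms along +x


def test_coarse_grid_warns():
    net = _cylinder_net(radius=1.5)
    with pytest.warns(UserWarning):
        rasterize_network(net, VoxelGrid.for_box(net.bounding_box, 4.0))


def test_susceptibility_linearity_and_hct_ratio():
    lum = np.ones((4, 4, 4), dtype=bool)
    so2 = np.full(lum.shape, 0.5)
    cap = susceptibility_map(lum, so2, np.full(lum.shape, 0.33))
    art = susceptibility_map(lum, so2, np.full(lum.shape, 0.44))
    assert np.allclose(cap / art, 0.33 / 0.44)
    # halving (1 - SO2) halves chi
    so2_hi = 1.0 - 0.5 * (1.0 - so2)
    half = susceptibility_map(lum, so2_hi, np.full(lum.shape, 0.33))
    assert np.allclose(half, 0.5 * cap)
    # fully oxygenated blood is susceptibility-matched
    assert np.all(susceptibility_map(lum, np.ones(lum.shape), np.full(lum.shape, 0.44)) == 0.0)
    with pytest.raises(ValidationError):
        susceptibility_map(lum, so2 + 1.0, np.full(lum.shape, 0.33))


def _periodic_cylinder_chi(n=128, r=6, dchi=4e-7, axis=2):
    idx = np.indices((n, n))
    c = n / 2 - 0.5
    mask2d = (idx[0] - c) ** 2 + (idx[1] - c) ** 2 <= r * r
    chi = np.zeros((n, n, n))
    if axis == 2:
        chi[mask2d, :] = dchi
    else:
        chi[:, mask2d] = dchi  # cylinder along x
    return chi, mask2d


@pytest.mark.parametrize(
    "b0_dir,factor",
    [((0.0, 0.0, 1.0), 1.0 / 3.0), ((1.0, 0.0, 0.0), -1.0 / 6.0)],
    ids=["parallel", "perpendicular"],
)
def test_dipole_cylinder_closed_form(b0_dir, factor):
    """Interior field of an infinite cylinder: Δχ·B0/3 (∥) and −Δχ·B0/6 (⊥)."""
    dchi, b0 = 4e-7, 3.0
    chi, mask2d = _periodic_cylinder_chi(dchi=dchi)
    db = dipole_convolve(chi, b0_dir, b0)
    n = chi.shape[0]
    idx = np.indices((n, n))
    c = n / 2 - 0.5
    core = (idx[0] - c) ** 2 + (idx[1] - c) ** 2 <= 3.0**2
    interior = db[core, :].mean()
    assert interior == pytest.approx(factor * dchi * b0, rel=0.05)


def test_dipole_linearity_zero_mean_and_uniform_chi():
    rng = np.random.default_rng(0)
    chi = rng.random((16, 16, 16)) * 1e-6
    a = dipole_convolve(chi, (0, 0, 1), 3.0)
    b = dipole_convolve(2.0 * chi, (0, 0, 1), 3.0)
    assert np.allclose(b, 2.0 * a)
    assert abs(a.mean()) < 1e-18
    assert np.allclose(dipole_convolve(np.full((8, 8, 8), 1e-6), (0, 0, 1), 3.0), 0.0, atol=1e-20)


def test_dipole_axis_equivariance():
    """Swapping the B0 axis x<->z equals transposing the chi volume."""
    rng = np.random.default_rng(1)
    chi = rng.random((12, 12, 12)) * 1e-6
    a = dipole_convolve(chi, (1, 0, 0), 3.0)
    b = dipole_convolve(chi.transpose(2, 1, 0), (0, 0, 1), 3.0).transpose(2, 1, 0)
    assert np.allclose(a, b, atol=1e-16)


def test_t2_formulas_and_monotonicity():
    assert t2_tissue(3.0) == pytest.approx(1.0 / (1.74 * 3.0 + 7.77), rel=1e-12)
    lum = np.zeros((2, 2, 2), dtype=bool)
    lum[0, 0, 0] = True
    so2 = np.zeros(lum.shape)
    so2[0, 0, 0] = 1.0
    t2 = t2_field(lum, so2, 3.0)
    assert t2[0, 0, 0] == pytest.approx(1.0 / (2.74 * 3.0 - 0.6), rel=1e-12)
    assert t2[1, 1, 1] == pytest.approx(t2_tissue(3.0))
    # lower SO2 -> shorter vascular T2
    so2[0, 0, 0] = 0.4
    assert t2_field(lum, so2, 3.0)[0, 0, 0] < t2[0, 0, 0]
    with pytest.raises(ValidationError):
        t2_field(lum, so2, 0.2)  # below the valid B0 domain


def test_hematocrit_map_from_edges():
    net = _cylinder_net()
    net.edges[0].hematocrit = 0.33
    maps = rasterize_network(net, VoxelGrid.for_box(net.bounding_box, 2.0))
    hct = hematocrit_map(net, maps)
    assert np.all(hct[maps.lumen_mask] == 0.33)
    assert np.all(hct[~maps.lumen_mask] == 0.0)
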