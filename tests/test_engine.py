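"""Spin-dynamics engine: initialization, stepping, routing, readout."""

import numpy as np
import pytest

from mvds.engine import (
    FlowRouter,
    advect_routing,
    initialize_spins,
    run_sequence,
    step,
)
from mvds.fields import VoxelGrid, build_field_maps, rasterize_network, t2_field, t2_tissue
from mvds.network import ValidationError, VascularNetwork, VesselEdge, VesselNode, VesselType
from mvds.sequence import SequenceParams


def test_asl_spins_all_inside_lumen(single_tube):
    maps = build_field_maps(single_tube, spacing=2.0)
    ens = initialize_spins(5000, maps, "asl", seed=0)
    ix, iy, iz = maps.grid.voxel_index(ens.positions)
    assert maps.lumen_mask[ix, iy, iz].all()
    assert ens.is_iv.all()
    assert np.all(ens.log_amp == 0.0) and np.all(ens.phase == 0.0)


def test_full_mode_iv_fraction_matches_lumen_fraction(single_tube):
    maps = build_field_maps(single_tube, spacing=2.0)
    n = 100_000
    ens = initialize_spins(n, maps, "full", seed=1)
    f = maps.lumen_mask.mean()
    # binomial 99% bound
    assert abs(ens.is_iv.mean() - f) < 2.58 * np.sqrt(f * (1 - f) / n)


def test_asl_requires_lumen(empty_maps):
    with pytest.raises(ValidationError):
        initialize_spins(100, empty_maps, "asl")


def test_static_spins_refocus_exactly(empty_maps):
    """Arbitrary static ΔB accumulates zero net phase at the echo."""
    rng = np.random.default_rng(0)
    empty_maps.delta_b = rng.normal(0.0, 1e-6, empty_maps.grid.shape)
    params = SequenceParams(dtheta1_deg=90.0, dtheta2_deg=90.0)
    ens = initialize_spins(500, empty_maps, "full", 3)
    srng = np.random.default_rng(4)
    for k in range(params.n_steps):
        step(ens, empty_maps, params, k, None, None, diffusivity=0.0, rng=srng)
    assert np.abs(ens.phase).max() < 1e-12


def test_homogeneous_decay_exact(empty_maps):
    """No gradient, no vessels: S(TE) = exp(-TE/T2_tissue) exactly."""
    params = SequenceParams(b=0.0, dtheta1_deg=90.0, dtheta2_deg=90.0)
    tr = run_sequence(None, empty_maps, params, "full", seed=0, n_spins=200)
    expected = np.exp(-16e-3 / t2_tissue(3.0))
    assert tr.s0 == pytest.approx(expected, rel=1e-10)
    assert np.allclose(tr.s_i, expected, rtol=1e-10)


def test_free_diffusion_matches_stejskal_tanner(empty_maps):
    params = SequenceParams(b=500.0, dtheta1_deg=90.0, dtheta2_deg=90.0)
    n = 20_000
    tr = run_sequence(None, empty_maps, params, "full", seed=2, n_spins=n)
    target = np.exp(-500.0 * 0.8e-3)
    # Monte-Carlo standard error of the attenuated magnitude
    se = np.sqrt((1.0 - target**2) / (2 * n)) / tr.s0
    assert np.all(np.abs(tr.ratios - target) < 3 * se + 3e-3)


def test_plug_flow_uniform_phase_does_not_attenuate(single_tube):
    """Coherent plug flow with no diffusion: |S_i| = |S0|."""
    from mvds.engine import SpinEnsemble

    maps = build_field_maps(single_tube, spacing=2.0)
    maps.delta_b[:] = 0.0
    params = SequenceParams(dtheta1_deg=90.0, dtheta2_deg=90.0)
    router = FlowRouter.from_network(single_tube)
    full = initialize_spins(2000, maps, "asl", seed=3, router=router)
    # keep spins that cannot reach the outlet during TE (speed 1 µm/ms, 16 ms)
    keep = full.positions[:, 0] < 150.0
    ens = SpinEnsemble(
        positions=full.positions[keep].copy(),
        log_amp=full.log_amp[keep].copy(),
        phase=full.phase[keep].copy(),
        is_iv=full.is_iv[keep].copy(),
        current_edge=full.current_edge[keep].copy(),
    )
    rng = np.random.default_rng(0)
    for k in range(params.n_steps):
        step(ens, maps, params, k, router, (1.0, 0.0, 0.0), diffusivity=0.0, rng=rng)
    # identical velocities -> identical gradient phase -> no dephasing
    assert np.ptp(ens.phase) < 1e-9
    s = np.abs(np.mean(np.exp(ens.log_amp + 1j * ens.phase)))
    s0 = np.abs(np.mean(np.exp(ens.log_amp)))
    assert s == pytest.approx(s0, rel=1e-12)


def test_iv_advection_along_tangent(single_tube):
    maps = build_field_maps(single_tube, spacing=2.0)
    params = SequenceParams(dtheta1_deg=90.0, dtheta2_deg=90.0)
    router = FlowRouter.from_network(single_tube)
    ens = initialize_spins(200, maps, "asl", seed=5)
    before = ens.positions.copy()
    step(ens, maps, params, 0, router, None, diffusivity=0.0, rng=np.random.default_rng(0))
    moved = ens.positions - before
    # speed 1 mm/s = 1 µm/ms -> 0.05 µm along +x per Δt (except rejected/routed spins)
    ok = np.isclose(moved[:, 0], 0.05) & np.isclose(moved[:, 1], 0.0) & np.isclose(moved[:, 2], 0.0)
    assert ok.mean() > 0.95


def test_iv_spins_confined_to_tube(single_tube):
    maps = build_field_maps(single_tube, spacing=2.0)
    params = SequenceParams(dtheta1_deg=90.0, dtheta2_deg=90.0)
    tr_router = FlowRouter.from_network(single_tube)
    ens = initialize_spins(1000, maps, "asl", seed=6)
    rng = np.random.default_rng(7)
    for k in range(100):
        step(ens, maps, params, k, tr_router, None, rng=rng)
    # radial distance from the tube axis never exceeds radius (+ initial half-voxel)
    d = np.hypot(ens.positions[:, 1] - 50.0, ens.positions[:, 2] - 50.0)
    assert d.max() <= 3.0 + np.sqrt(3.0)  # radius + initial voxel-quantization slack


def _y_network(speed_a=1.0, speed_b=1.0):
    nodes = [
        VesselNode(0, (10.0, 50.0, 50.0), 3.0),
        VesselNode(1, (60.0, 50.0, 50.0), 3.0),
        VesselNode(2, (110.0, 80.0, 50.0), 3.0),
        VesselNode(3, (110.0, 20.0, 50.0), 3.0),
    ]
    edges = [
        VesselEdge((0, 1), vessel_type=VesselType.CAPILLARY, speed=1.0, so2=0.7, hematocrit=0.33),
        VesselEdge((1, 2), vessel_type=VesselType.CAPILLARY, speed=speed_a, so2=0.7, hematocrit=0.33),
        VesselEdge((1, 3), vessel_type=VesselType.CAPILLARY, speed=speed_b, so2=0.7, hematocrit=0.33),
    ]
    return VascularNetwork(nodes=nodes, edges=edges, bounding_box=(120.0, 100.0, 100.0))


def test_bifurcation_routing_proportional_to_flow():
    router = FlowRouter.from_network(_y_network())
    rng = np.random.default_rng(0)
    n = 10_000
    new_edges, _ = router.route(np.zeros(n, dtype=int), np.full(n, 0.1), rng)
    frac = (new_edges == 1).mean()
    assert abs(frac - 0.5) < 2.58 * np.sqrt(0.25 / n)
    # unequal flows shift the split
    router2 = FlowRouter.from_network(_y_network(speed_a=3.0, speed_b=1.0))
    new2, _ = router2.route(np.zeros(n, dtype=int), np.full(n, 0.1), rng)
    assert (new2 == 1).mean() > 0.70


def test_single_tube_never_reroutes_midstream(single_tube):
    router = FlowRouter.from_network(single_tube)
    maps = build_field_maps(single_tube, spacing=2.0)
    ens = initialize_spins(500, maps, "asl", seed=8)
    # spins well inside the tube keep their edge
    advect_routing(ens, single_tube, router)
    assert np.all(ens.current_edge == 0)


def test_reinjection_conserves_spin_count(single_tube):
    maps = build_field_maps(single_tube, spacing=2.0)
    ens = initialize_spins(300, maps, "asl", seed=9)
    # push every spin past the downstream end
    ens.positions[:, 0] = 195.0
    n_before = ens.n
    advect_routing(ens, single_tube)
    assert ens.n == n_before
    assert np.all(ens.current_edge == 0)  # re-injected at the only (inlet) edge
    assert np.all(ens.positions[:, 0] <= 190.0)


def test_antipodal_direction_magnitudes_identical(empty_maps):
    """With a refocused (zero) ΔB field, S(u) and S(-u) agree exactly."""
    params = SequenceParams(
        b=500.0, directions=np.array([[0.0, 0.0, 1.0], [0.0, 0.0, -1.0], [1.0, 0.0, 0.0]])
    )
    tr = run_sequence(None, empty_maps, params, "full", seed=11, n_spins=2000)
    assert tr.s_i[0] == pytest.approx(tr.s_i[1], abs=1e-12)


def test_signal_bounded_by_slowest_decay(empty_maps):
    params = SequenceParams(b=1000.0, dtheta1_deg=90.0, dtheta2_deg=90.0)
    tr = run_sequence(None, empty_maps, params, "full", seed=12, n_spins=2000)
    bound = np.exp(-16e-3 / t2_tissue(3.0))
    assert tr.s0 <= bound + 1e-12
    assert np.all(tr.s_i <= bound + 1e-12)


def test_time_step_convergence(empty_maps):
    """Halving Δt moves the readout by less than the Monte-Carlo error."""
    n = 20_000
    target = np.exp(-500.0 * 0.8e-3)
    ratios = []
    for dt in (0.05, 0.025):
        params = SequenceParams(b=500.0, dt=dt, dtheta1_deg=90.0, dtheta2_deg=90.0)
        tr = run_sequence(None, empty_maps, params, "full", seed=13, n_spins=n)
        ratios.append(tr.ratios.mean())
    se = np.sqrt((1.0 - target**2) / (2 * n)) / np.exp(-16e-3 / t2_tissue(3.0))
    assert abs(ratios[0] - ratios[1]) < 3 * se + 2e-3


def test_rotation_equivariance_small_bed():
    """Rotating the bed and the gradient directions by 90° about z leaves S unchanged."""
    from mvds.beds import generate_random_bed
    from mvds.experiments import default_forest, prepare_sample

    forest = default_forest(0, n_records=300)
    net = generate_random_bed(40, box=(100.0, 100.0, 100.0), seed=14)
    sample = prepare_sample(net, forest, spacing=2.0)
    sample.with_field(3.0)
    dirs = np.array([[1.0, 0.0, 0.0], [0.0, 0.0, 1.0]])
    params = SequenceParams(directions=dirs)
    tr = run_sequence(net, sample.maps, params, "asl", seed=15, n_spins=5000)

    # rotate node coordinates (x, y) -> (y, L - x); box is square in-plane
    rot_nodes = [
        VesselNode(n.id, (n.position[1], 100.0 - n.position[0], n.position[2]), n.radius)
        for n in net.nodes
    ]
    rot = VascularNetwork(nodes=rot_nodes, edges=net.edges, bounding_box=net.bounding_box)
    sample2 = prepare_sample(rot, forest, spacing=2.0)
    sample2.with_field(3.0)
    rot_dirs = np.array([[0.0, -1.0, 0.0], [0.0, 0.0, 1.0]])
    tr2 = run_sequence(rot, sample2.maps, SequenceParams(directions=rot_dirs), "asl", seed=15, n_spins=5000)
    assert tr2.ratios == pytest.approx(tr.ratios, abs=0.02)


def test_record_timeseries(empty_maps):
    params = SequenceParams(b=100.0, dtheta1_deg=90.0, dtheta2_deg=90.0)
    tr = run_sequence(None, empty_maps, params, "full", seed=16, n_spins=500, record_every=80)
    assert tr.signal is not None
    assert tr.signal.shape == (params.n_steps // 80, len(params.directions) + 1)
    # magnitude decays over time
    mags = np.abs(tr.signal[:, 0])
    assert np.all(np.diff(mags) < 0)
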