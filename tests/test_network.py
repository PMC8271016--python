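"""Graph model, file round-trips, vessel typing and segment geometry."""

import numpy as np
import pytest

from mvds.beds import generate_random_bed
from mvds.network import (
    FormatError,
    ValidationError,
    VascularNetwork,
    VesselEdge,
    VesselNode,
    VesselType,
    assign_vessel_types,
    load_network,
    save_network,
    segment_geometry,
)


@pytest.mark.parametrize("fmt", ["json", "graphml"])
def test_round_trip_preserves_structure_and_attributes(tmp_path, fmt):
    net = generate_random_bed(25, seed=7)
    net.edges[0].speed = 1.25
    net.edges[0].po2 = 55.5
    net.edges[0].so2 = 0.625
    net.edges[0].hematocrit = 0.33
    path = tmp_path / f"net.{fmt}"
    save_network(net, path, fmt)
    back = load_network(path, fmt)
    assert back.n_nodes == net.n_nodes and back.n_edges == net.n_edges
    assert np.array_equal(back.positions(), net.positions())
    orig = {tuple(sorted(e.node_pair)): e for e in net.edges}
    for e in back.edges:
        o = orig[tuple(sorted(e.node_pair))]
        assert e.vessel_type == o.vessel_type
        assert e.speed == o.speed and e.po2 == o.po2
        assert e.so2 == o.so2 and e.hematocrit == o.hematocrit


def test_edge_referencing_missing_node_is_rejected(tmp_path):
    path = tmp_path / "bad.json"
    path.write_text(
        '{"format": "mvds-network", "version": 1, "bounding_box": [10, 10, 10],'
        ' "nodes": [{"id": 0, "pos": [1, 1, 1], "radius": 2.0}],'
        ' "edges": [{"src": 0, "dst": 5}]}'
    )
    with pytest.raises(ValidationError):
        load_network(path)


def test_garbage_file_raises_format_error(tmp_path):
    path = tmp_path / "bad.json"
    path.write_text("not json at all {{{")
    with pytest.raises(FormatError):
        load_network(path)


def test_toy_two_node_file_has_100um_edge(tmp_path, toy_network):
    path = tmp_path / "toy.json"
    save_network(toy_network, path)
    net = load_network(path)
    geo = segment_geometry(net)
    assert geo["length"][0] == pytest.approx(100.0)


def test_non_finite_attribute_refused(tmp_path, toy_network):
    toy_network.edges[0].speed = float("nan")
    with pytest.raises(ValidationError):
        save_network(toy_network, tmp_path / "x.json")


def test_empty_edge_network_round_trips(tmp_path):
    net = VascularNetwork(
        nodes=[VesselNode(0, (1.0, 1.0, 1.0), 2.0)], edges=[], bounding_box=(10.0, 10.0, 10.0)
    )
    save_network(net, tmp_path / "e.json")
    assert load_network(tmp_path / "e.json").n_edges == 0


def test_assign_vessel_types_threshold_and_split():
    # small radii -> all capillary
    net = generate_random_bed(50, radius_range=(2.0, 2.5), seed=0)
    assign_vessel_types(net, seed=1)
    assert all(e.vessel_type is VesselType.CAPILLARY for e in net.edges)
    # large radii -> artery/vein with p = 1/2 each
    big = generate_random_bed(1000, radius_range=(9.0, 11.0), seed=0)
    assign_vessel_types(big, seed=1)
    n_art = sum(e.vessel_type is VesselType.ARTERY for e in big.edges)
    assert all(e.vessel_type is not VesselType.CAPILLARY for e in big.edges)
    # binomial 99% bound around 500
    assert abs(n_art - 500) < 2.58 * np.sqrt(1000 * 0.25)


def test_assign_vessel_types_deterministic_given_seed():
    a = generate_random_bed(200, radius_range=(1.0, 10.0), seed=3)
    b = generate_random_bed(200, radius_range=(1.0, 10.0), seed=3)
    assign_vessel_types(a, seed=11)
    assign_vessel_types(b, seed=11)
    assert [e.vessel_type for e in a.edges] == [e.vessel_type for e in b.edges]


def test_segment_geometry_hand_cases():
    net = VascularNetwork(
        nodes=[VesselNode(0, (0.0, 0.0, 0.0), 2.0), VesselNode(1, (0.0, 0.0, 50.0), 4.0)],
        edges=[VesselEdge((0, 1), flow_direction=1)],
        bounding_box=(50.0, 50.0, 50.0),
    )
    geo = segment_geometry(net)
    assert geo["length"][0] == pytest.approx(50.0)
    assert geo["tangent"][0] == pytest.approx([0.0, 0.0, 1.0])
    assert geo["radius"][0] == pytest.approx(3.0)
    assert geo["depth"][0] == pytest.approx(25.0)  # |z| of midpoint, z-down


def test_segment_geometry_unit_tangents_and_reversal_symmetry():
    net = generate_random_bed(40, seed=5)
    geo = segment_geometry(net)
    assert np.allclose(np.linalg.norm(geo["tangent"], axis=1), 1.0)
    # reversing node order while flipping flow sign preserves oriented geometry
    for e in net.edges:
        e.node_pair = (e.node_pair[1], e.node_pair[0])
        e.flow_direction *= -1
    geo2 = segment_geometry(net)
    assert np.allclose(geo2["length"], geo["length"])
    assert np.allclose(geo2["tangent"], geo["tangent"])


def test_zero_length_edge_rejected():
    net = VascularNetwork(
        nodes=[VesselNode(0, (1.0, 1.0, 1.0), 2.0), VesselNode(1, (1.0, 1.0, 1.0), 2.0)],
        edges=[VesselEdge((0, 1))],
        bounding_box=(10.0, 10.0, 10.0),
    )
    with pytest.raises(ValidationError):
        segment_geometry(net)
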