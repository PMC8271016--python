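"""Vascular network graph model and file I/O.

A microvascular network is represented as a geometric graph: nodes carry a
3-D centerline position (µm) and a local vessel radius (µm); edges connect
node pairs and carry the per-segment attributes the simulator needs
(vessel type, flow orientation, blood speed, oxygenation, hematocrit).

Coordinates are right-handed, in micrometres, with z increasing with
cortical depth and the origin at the top corner of the domain.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np


class VesselType(str, Enum):
    ARTERY = "artery"
    VEIN = "vein"
    CAPILLARY = "capillary"


class ValidationError(ValueError):
    """A network or attribute violates a structural invariant."""


class FormatError(ValueError):
    """A network file could not be parsed in the declared format."""


@dataclass(frozen=True)
class VesselNode:
    """A centerline point with a local vessel radius."""

    id: int
    position: tuple[float, float, float]
    radius: float

    def validate(self) -> None:
        if not all(math.isfinite(c) for c in self.position):
            raise ValidationError(f"node {self.id}: non-finite position {self.position}")
        if not (math.isfinite(self.radius) and self.radius > 0):
            raise ValidationError(f"node {self.id}: radius must be finite and > 0, got {self.radius}")


@dataclass
class VesselEdge:
    """A vessel segment between two nodes.

    ``flow_direction`` is +1 when blood flows from the first to the second
    node of ``node_pair`` and -1 otherwise.  ``speed`` is the centerline
    blood speed in mm/s, ``po2`` the oxygen partial pressure in mmHg,
    ``so2`` the hemoglobin saturation fraction and ``hematocrit`` the
    volume fraction of red blood cells.
    """

    node_pair: tuple[int, int]
    branch_id: int = 0
    vessel_type: VesselType | None = None
    flow_direction: int = 1
    speed: float | None = None  # mm/s
    po2: float | None = None  # mmHg
    so2: float | None = None  # fraction
    hematocrit: float | None = None  # fraction

    def validate(self) -> None:
        if self.node_pair[0] == self.node_pair[1]:
            raise ValidationError(f"self-loop edge at node {self.node_pair[0]}")
        if self.flow_direction not in (-1, 1):
            raise ValidationError(f"flow_direction must be +1 or -1, got {self.flow_direction}")
        for name in ("speed", "po2", "so2", "hematocrit"):
            v = getattr(self, name)
            if v is not None and not math.isfinite(v):
                raise ValidationError(f"edge {self.node_pair}: non-finite {name}={v}")
        if self.speed is not None and self.speed < 0:
            raise ValidationError(f"edge {self.node_pair}: speed must be >= 0")
        if self.po2 is not None and self.po2 < 0:
            raise ValidationError(f"edge {self.node_pair}: po2 must be >= 0")
        if self.so2 is not None and not (0.0 <= self.so2 <= 1.0):
            raise ValidationError(f"edge {self.node_pair}: so2 must lie in [0, 1]")


@dataclass
class VascularNetwork:
    """Geometric/topological model of a microvascular bed."""

    nodes: list[VesselNode]
    edges: list[VesselEdge]
    bounding_box: tuple[float, float, float]  # extent in µm from the origin

    def __post_init__(self) -> None:
        self._index = {n.id: i for i, n in enumerate(self.nodes)}

    # -- accessors ---------------------------------------------------------

    def node(self, node_id: int) -> VesselNode:
        return self.nodes[self._index[node_id]]

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def positions(self) -> np.ndarray:
        return np.array([n.position for n in self.nodes], dtype=float).reshape(-1, 3)

    def edge_radius(self, edge: VesselEdge) -> float:
        """Edge radius = mean of endpoint node radii."""
        a, b = edge.node_pair
        return 0.5 * (self.node(a).radius + self.node(b).radius)

    # -- validation --------------------------------------------------------

    def validate(self) -> "VascularNetwork":
        if len(self._index) != len(self.nodes):
            raise ValidationError("duplicate node ids")
        for n in self.nodes:
            n.validate()
            for c, ext in zip(n.position, self.bounding_box):
                if c < -1e-9 or c > ext + 1e-9:
                    raise ValidationError(f"node {n.id} at {n.position} outside bounding box {self.bounding_box}")
        for e in self.edges:
            e.validate()
            for nid in e.node_pair:
                if nid not in self._index:
                    raise ValidationError(f"edge {e.node_pair} references missing node {nid}")
        return self

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        for n in self.nodes:
            g.add_node(n.id, x=n.position[0], y=n.position[1], z=n.position[2], radius=n.radius)
        for e in self.edges:
            attrs = {
                "branch_id": e.branch_id,
                "flow_direction": e.flow_direction,
            }
            if e.vessel_type is not None:
                attrs["vessel_type"] = e.vessel_type.value
            for name in ("speed", "po2", "so2", "hematocrit"):
                v = getattr(e, name)
                if v is not None:
                    attrs[name] = v
            g.add_edge(*e.node_pair, **attrs)
        # GraphML cannot carry list-valued graph attributes
        g.graph["bounding_box"] = ",".join(repr(float(c)) for c in self.bounding_box)
        return g


# ---------------------------------------------------------------------------
# Serialization: JSON dialect (canonical) and GraphML (export/import)
# ---------------------------------------------------------------------------

_EDGE_FLOATS = ("speed", "po2", "so2", "hematocrit")


def _network_to_dict(net: VascularNetwork) -> dict:
    return {
        "format": "mvds-network",
        "version": 1,
        "bounding_box": list(net.bounding_box),
        "nodes": [
            {"id": n.id, "pos": list(n.position), "radius": n.radius} for n in net.nodes
        ],
        "edges": [
            {
                "src": e.node_pair[0],
                "dst": e.node_pair[1],
                "branch_id": e.branch_id,
                "vessel_type": e.vessel_type.value if e.vessel_type else None,
                "flow_direction": e.flow_direction,
                **{k: getattr(e, k) for k in _EDGE_FLOATS},
            }
            for e in net.edges
        ],
    }


def _network_from_dict(d: dict) -> VascularNetwork:
    try:
        nodes = [
            VesselNode(id=int(n["id"]), position=tuple(float(c) for c in n["pos"]), radius=float(n["radius"]))
            for n in d["nodes"]
        ]
        edges = []
        for e in d["edges"]:
            vt = e.get("vessel_type")
            edges.append(
                VesselEdge(
                    node_pair=(int(e["src"]), int(e["dst"])),
                    branch_id=int(e.get("branch_id", 0)),
                    vessel_type=VesselType(vt) if vt else None,
                    flow_direction=int(e.get("flow_direction", 1)),
                    **{k: (None if e.get(k) is None else float(e[k])) for k in _EDGE_FLOATS},
                )
            )
        box = tuple(float(c) for c in d["bounding_box"])
    except (KeyError, TypeError, ValueError) as exc:
        if isinstance(exc, ValidationError):
            raise
        raise FormatError(f"malformed network dictionary: {exc}") from exc
    return VascularNetwork(nodes=nodes, edges=edges, bounding_box=box).validate()


def save_network(network: VascularNetwork, path: str | Path, format: str = "json") -> None:
    """Write a network to disk; the emitted file loads back identically.

    ``format`` is ``"json"`` (canonical dialect), ``"graphml"`` or ``"vtk"``
    (legacy ASCII poly-line export, write-only, for visualization).
    """
    network.validate()
    path = Path(path)
    if format == "json":
        path.write_text(json.dumps(_network_to_dict(network), indent=1))
    elif format == "graphml":
        nx.write_graphml(network.to_networkx(), path)
    elif format == "vtk":
        _write_vtk_polylines(network, path)
    else:
        raise FormatError(f"unknown format {format!r}")


def load_network(path: str | Path, format: str = "json") -> VascularNetwork:
    """Load and validate a network from ``path``."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "json":
        try:
            d = json.loads(path.read_text())
        except json.JSONDecodeError as exc:
            raise FormatError(f"{path}: not valid JSON: {exc}") from exc
        return _network_from_dict(d)
    if format == "graphml":
        try:
            g = nx.read_graphml(path)
        except Exception as exc:  # networkx raises several parse error types
            raise FormatError(f"{path}: not valid GraphML: {exc}") from exc
        return _network_from_networkx(g)
    raise FormatError(f"unknown format {format!r}")


def _network_from_networkx(g: nx.Graph) -> VascularNetwork:
    nodes = [
        VesselNode(id=int(nid), position=(float(a["x"]), float(a["y"]), float(a["z"])), radius=float(a["radius"]))
        for nid, a in g.nodes(data=True)
    ]
    edges = []
    for u, v, a in g.edges(data=True):
        vt = a.get("vessel_type")
        edges.append(
            VesselEdge(
                node_pair=(int(u), int(v)),
                branch_id=int(a.get("branch_id", 0)),
                vessel_type=VesselType(vt) if vt else None,
                flow_direction=int(a.get("flow_direction", 1)),
                **{k: (float(a[k]) if k in a else None) for k in _EDGE_FLOATS},
            )
        )
    box = g.graph.get("bounding_box")
    if box is None:
        raise FormatError("GraphML file lacks a bounding_box graph attribute")
    if isinstance(box, str):
        box = [float(c) for c in box.strip("[]").split(",")]
    return VascularNetwork(nodes=nodes, edges=edges, bounding_box=tuple(float(c) for c in box)).validate()


def _write_vtk_polylines(net: VascularNetwork, path: Path) -> None:
    lines = [
        "# vtk DataFile Version 3.0",
        "mvds vascular network",
        "ASCII",
        "DATASET POLYDATA",
        f"POINTS {net.n_nodes} float",
    ]
    order = {n.id: i for i, n in enumerate(net.nodes)}
    lines += [" ".join(f"{c:.6f}" for c in n.position) for n in net.nodes]
    lines.append(f"LINES {net.n_edges} {3 * net.n_edges}")
    lines += [f"2 {order[e.node_pair[0]]} {order[e.node_pair[1]]}" for e in net.edges]
    lines.append(f"POINT_DATA {net.n_nodes}")
    lines.append("SCALARS radius float 1")
    lines.append("LOOKUP_TABLE default")
    lines += [f"{n.radius:.6f}" for n in net.nodes]
    path.write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Vessel typing and geometry
# ---------------------------------------------------------------------------


def assign_vessel_types(
    network: VascularNetwork, radius_threshold: float = 3.0, seed: int | np.random.Generator = 0
) -> VascularNetwork:
    """Label each edge capillary / artery / vein by radius thresholding.

    Edges whose mean endpoint radius is at or below ``radius_threshold``
    (default 3 µm) are capillaries; larger vessels are assigned artery or
    vein independently with probability 1/2 each under ``seed``.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    network.validate()
    coin = rng.random(network.n_edges)
    for e, c in zip(network.edges, coin):
        r = network.edge_radius(e)
        if r <= radius_threshold:
            e.vessel_type = VesselType.CAPILLARY
        else:
            e.vessel_type = VesselType.ARTERY if c < 0.5 else VesselType.VEIN
    return network


def segment_geometry(network: VascularNetwork) -> dict[str, np.ndarray]:
    """Per-edge geometry table used by physiology and rasterization.

    Returns arrays over edges: ``length`` (µm), ``tangent`` (unit vector
    oriented with flow), ``midpoint`` (µm), ``radius`` (µm, mean of
    endpoint radii), ``depth`` (µm below the top z=0 face), and the
    flow-oriented endpoints ``p_up``/``p_down``.
    """
    network.validate()
    n = network.n_edges
    length = np.empty(n)
    tangent = np.empty((n, 3))
    midpoint = np.empty((n, 3))
    radius = np.empty(n)
    p_up = np.empty((n, 3))
    p_down = np.empty((n, 3))
    for i, e in enumerate(network.edges):
        a = np.asarray(network.node(e.node_pair[0]).position, dtype=float)
        b = np.asarray(network.node(e.node_pair[1]).position, dtype=float)
        if e.flow_direction < 0:
            a, b = b, a
        d = b - a
        L = float(np.linalg.norm(d))
        if L == 0.0:
            raise ValidationError(f"zero-length edge {e.node_pair}")
        length[i] = L
        tangent[i] = d / L
        midpoint[i] = 0.5 * (a + b)
        radius[i] = network.edge_radius(e)
        p_up[i] = a
        p_down[i] = b
    # depth below the top face (z = 0), z-down convention
    depth = np.abs(midpoint[:, 2]) if n else np.empty(0)
    return {
        "length": length,
        "tangent": tangent,
        "midpoint": midpoint,
        "radius": radius,
        "depth": depth,
        "p_up": p_up,
        "p_down": p_down,
    }
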