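"""Synthetic capillary-bed generators.

Two cohorts of straight capillary segments emulate the key geometric
contrast between healthy cortex and post-occlusion angiogenesis:

* *random* beds — segment orientations uniform on the sphere, the
  isotropic arrangement expected in healthy microvasculature;
* *radial* beds — segment tangents aligned with the in-plane (lateral)
  radial direction away from a vertical axis, emulating the radially
  re-organized capillaries observed around a micro-infarct locus.

Segments are 2-node straight tubes with radii drawn uniformly from
2–4 µm and independent ±1 flow orientations.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .network import ValidationError, VascularNetwork, VesselEdge, VesselNode, VesselType

DEFAULT_BOX = (200.0, 200.0, 200.0)  # µm
DEFAULT_RADIUS_RANGE = (2.0, 4.0)  # µm
DEFAULT_LENGTH_RANGE = (30.0, 60.0)  # µm
DEFAULT_JITTER_DEG = 15.0


def _check_ranges(radius_range, length_range) -> None:
    lo, hi = radius_range
    if not (0.0 < lo <= hi and np.isfinite(hi)):
        raise ValidationError(f"radius_range must be positive and ordered, got {radius_range}")
    lo, hi = length_range
    if not (0.0 < lo <= hi and np.isfinite(hi)):
        raise ValidationError(f"length_range must be positive and ordered, got {length_range}")


def _build_bed(midpoints, tangents, lengths, radii, flow_dirs, box) -> VascularNetwork:
    box = np.asarray(box, dtype=float)
    # shrink along the segment axis (never clip per-coordinate, which would
    # distort the orientation) so both endpoints stay inside the box
    half = 0.5 * lengths
    with np.errstate(divide="ignore", invalid="ignore"):
        step_plus = np.where(tangents > 0, (box - midpoints) / tangents, (0.0 - midpoints) / tangents)
        step_plus = np.where(tangents == 0, np.inf, step_plus)
    cap_plus = np.nanmin(step_plus, axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        step_minus = np.where(tangents < 0, (box - midpoints) / tangents, (0.0 - midpoints) / tangents)
        step_minus = np.where(tangents == 0, np.inf, step_minus)
    cap_minus = np.nanmin(step_minus, axis=1)
    b_len = np.minimum(half, np.maximum(cap_plus, 0.0))
    a_len = np.minimum(half, np.maximum(cap_minus, 0.0))
    # degenerate all-shrunk segments (midpoint on a face): keep a 1 µm stub
    tiny = (a_len + b_len) < 1.0
    if np.any(tiny):
        b_len[tiny] = np.maximum(b_len[tiny], np.minimum(1.0, np.maximum(cap_plus[tiny], 0.0)))
        a_len[tiny] = np.maximum(a_len[tiny], np.minimum(1.0, np.maximum(cap_minus[tiny], 0.0)))
    a = midpoints - a_len[:, None] * tangents
    b = midpoints + b_len[:, None] * tangents
    a = np.clip(a, 0.0, box)  # guard against floating-point overshoot only
    b = np.clip(b, 0.0, box)
    nodes, edges = [], []
    for i in range(len(radii)):
        nodes.append(VesselNode(id=2 * i, position=tuple(a[i]), radius=float(radii[i])))
        nodes.append(VesselNode(id=2 * i + 1, position=tuple(b[i]), radius=float(radii[i])))
        edges.append(
            VesselEdge(
                node_pair=(2 * i, 2 * i + 1),
                branch_id=i,
                vessel_type=VesselType.CAPILLARY,
                flow_direction=int(flow_dirs[i]),
            )
        )
    return VascularNetwork(nodes=nodes, edges=edges, bounding_box=tuple(float(c) for c in box)).validate()


def _uniform_sphere(rng: np.random.Generator, n: int) -> np.ndarray:
    z = rng.uniform(-1.0, 1.0, n)
    phi = rng.uniform(0.0, 2.0 * np.pi, n)
    s = np.sqrt(1.0 - z**2)
    return np.column_stack([s * np.cos(phi), s * np.sin(phi), z])


def generate_random_bed(
    n_segments: int = 200,
    box=DEFAULT_BOX,
    radius_range=DEFAULT_RADIUS_RANGE,
    length_range=DEFAULT_LENGTH_RANGE,
    seed: int | np.random.Generator = 0,
) -> VascularNetwork:
    """Randomly oriented capillary bed (healthy-like isotropic geometry)."""
    if n_segments < 1:
        raise ValidationError("n_segments must be >= 1")
    _check_ranges(radius_range, length_range)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    box = np.asarray(box, dtype=float)
    mid = rng.uniform(0.0, 1.0, (n_segments, 3)) * box
    tan = _uniform_sphere(rng, n_segments)
    lengths = rng.uniform(*length_range, n_segments)
    radii = rng.uniform(*radius_range, n_segments)
    flow = rng.choice([-1, 1], n_segments)
    return _build_bed(mid, tan, lengths, radii, flow, box)


def generate_radial_bed(
    n_segments: int = 200,
    box=DEFAULT_BOX,
    radius_range=DEFAULT_RADIUS_RANGE,
    length_range=DEFAULT_LENGTH_RANGE,
    center_axis: tuple[float, float] | None = None,
    angular_jitter_deg: float = DEFAULT_JITTER_DEG,
    seed: int | np.random.Generator = 0,
) -> VascularNetwork:
    """Radially oriented capillary bed (post-occlusion-like geometry).

    Each segment's tangent points along the lateral (xy-plane) radial
    direction from the vertical ``center_axis`` through the segment
    midpoint, perturbed by wrapped-normal jitter of width
    ``angular_jitter_deg`` on the in-plane angle.
    """
    if n_segments < 1:
        raise ValidationError("n_segments must be >= 1")
    if angular_jitter_deg < 0:
        raise ValidationError("angular_jitter_deg must be >= 0")
    _check_ranges(radius_range, length_range)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    box = np.asarray(box, dtype=float)
    if center_axis is None:
        center_axis = (0.5 * box[0], 0.5 * box[1])
    if not (0.0 <= center_axis[0] <= box[0] and 0.0 <= center_axis[1] <= box[1]):
        raise ValidationError(f"center_axis {center_axis} outside box")
    mid = rng.uniform(0.0, 1.0, (n_segments, 3)) * box
    d = mid[:, :2] - np.asarray(center_axis)
    base_angle = np.arctan2(d[:, 1], d[:, 0])
    # midpoints exactly on the axis get an arbitrary (random) radial direction
    on_axis = np.hypot(d[:, 0], d[:, 1]) < 1e-12
    base_angle[on_axis] = rng.uniform(0.0, 2.0 * np.pi, int(on_axis.sum()))
    angle = base_angle + rng.normal(0.0, np.deg2rad(angular_jitter_deg), n_segments)
    tan = np.column_stack([np.cos(angle), np.sin(angle), np.zeros(n_segments)])
    lengths = rng.uniform(*length_range, n_segments)
    radii = rng.uniform(*radius_range, n_segments)
    flow = rng.choice([-1, 1], n_segments)
    return _build_bed(mid, tan, lengths, radii, flow, box)


def vascular_volume_fraction(network: VascularNetwork) -> float:
    """Total cylinder volume of all segments over the bounding-box volume."""
    from .network import segment_geometry

    geo = segment_geometry(network)
    vol = float(np.sum(np.pi * geo["radius"] ** 2 * geo["length"]))
    bx = np.prod(network.bounding_box)
    return vol / bx


def generate_cohorts(
    n_per_group: int = 30,
    n_segments: int = 200,
    box=DEFAULT_BOX,
    seed: int = 0,
    out_dir: str | Path | None = None,
    **kwargs,
) -> tuple[list[VascularNetwork], list[VascularNetwork]]:
    """Generate the two synthetic cohorts (random- and radial-oriented).

    Per-sample seeds are spawned deterministically from the master seed.
    If ``out_dir`` is given, networks are saved as JSON along with a
    manifest recording seeds and generator parameters.
    """
    if n_per_group < 2:
        raise ValidationError("n_per_group must be >= 2")
    master = np.random.SeedSequence(seed)
    children = master.spawn(2 * n_per_group)
    random_beds = [
        generate_random_bed(n_segments, box, seed=np.random.default_rng(children[i]), **kwargs)
        for i in range(n_per_group)
    ]
    radial_beds = [
        generate_radial_bed(n_segments, box, seed=np.random.default_rng(children[n_per_group + i]), **kwargs)
        for i in range(n_per_group)
    ]
    if out_dir is not None:
        from .network import save_network

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        manifest = {
            "seed": seed,
            "n_per_group": n_per_group,
            "n_segments": n_segments,
            "box": list(np.asarray(box, dtype=float)),
            "files": [],
        }
        for group, beds in (("random", random_beds), ("radial", radial_beds)):
            for i, bed in enumerate(beds):
                fname = f"{group}_{i:03d}.json"
                save_network(bed, out / fname, "json")
                manifest["files"].append(fname)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return random_beds, radial_beds
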