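"""Monte-Carlo spin dynamics: diffusion, advection, relaxation, phase.

Hydrogen spins random-walk through the voxelized domain.  Extravascular
(EV) spins diffuse freely (D = 0.8 µm²/ms) in an effectively infinite
medium (periodic field sampling, continuous coordinates); intravascular
(IV) spins additionally advect along their vessel's flow-oriented
tangent and are confined to the vessel lumen.  Exchange across the
vessel wall is negligible on the echo-time scale, enforced by rejecting
any proposed crossing of the lumen boundary (the spin keeps its previous
position for that step).

Per step of Δt, each spin's log-amplitude decays by Δt/T2 at its
location and its phase advances by d·γ·Δt·[ΔB(x) + G·(u·(x − x_c))],
where d = +1 before the 180° pulse and −1 after, and the gradient term
is active only while a lobe is on.  The voxel signal is the magnitude of
the ensemble-averaged complex amplitude.

Because spin trajectories are shared across gradient directions (common
random numbers), the engine evolves the walk once and accumulates the
per-spin vector q = Σ_n c_n·(x_n − x_c)·Δt-weighted positions; the
direction-i readout is then |⟨exp(α + i(φ_B + γ·G·u_i·q))⟩|, identical
to re-running the sequence per direction with the same seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .fields import FieldMaps, VoxelGrid
from .network import ValidationError, VascularNetwork, segment_geometry
from .sequence import SequenceParams, step_schedule

DEFAULT_DIFFUSIVITY = 0.8  # µm²/ms, free water at body temperature
DEFAULT_N_SPINS = 50_000  # desk-scale default; 1e6 reproduces full scale


# ---------------------------------------------------------------------------
# Network topology arrays for advection routing
# ---------------------------------------------------------------------------


@dataclass
class FlowRouter:
    """Flow-weighted routing of IV spins across the vessel graph.

    A spin advecting past its edge's downstream node moves onto an
    outgoing edge of that node with probability proportional to
    volumetric flow (speed·πr²); at a terminal node (or domain exit) it
    is re-injected at a flow-weighted inlet with amplitude and phase
    preserved, conserving spin count.
    """

    p_up: np.ndarray  # (E,3) flow-upstream endpoint, µm
    tangent: np.ndarray  # (E,3) unit, flow-oriented
    length: np.ndarray  # (E,)
    radius: np.ndarray  # (E,)
    speed: np.ndarray  # (E,) µm/ms
    down_node: np.ndarray  # (E,) node id downstream
    out_edges: dict  # node id -> (edge index array, probability array)
    inlet_edges: np.ndarray  # candidate re-injection edges
    inlet_probs: np.ndarray
    n_reinjected: int = 0

    @classmethod
    def from_network(cls, network: VascularNetwork) -> "FlowRouter":
        geo = segment_geometry(network)
        E = network.n_edges
        speed = np.array([e.speed if e.speed is not None else 0.0 for e in network.edges])
        up_node = np.empty(E, dtype=np.int64)
        down_node = np.empty(E, dtype=np.int64)
        for i, e in enumerate(network.edges):
            a, b = e.node_pair
            up_node[i], down_node[i] = (a, b) if e.flow_direction > 0 else (b, a)
        flow = speed * np.pi * geo["radius"] ** 2
        out_edges: dict = {}
        for i in range(E):
            out_edges.setdefault(up_node[i], []).append(i)
        out_tables = {}
        for node, idxs in out_edges.items():
            idxs = np.asarray(idxs)
            w = flow[idxs]
            tot = w.sum()
            p = w / tot if tot > 0 else np.full(len(idxs), 1.0 / len(idxs))
            out_tables[node] = (idxs, p)
        # inlets: edges whose upstream node receives no flow
        has_in = set(down_node.tolist())
        inlet = np.array([i for i in range(E) if up_node[i] not in has_in], dtype=np.int64)
        if inlet.size == 0:  # closed loops: allow re-injection anywhere
            inlet = np.arange(E)
        wi = flow[inlet]
        pi = wi / wi.sum() if wi.sum() > 0 else np.full(inlet.size, 1.0 / inlet.size)
        return cls(
            p_up=geo["p_up"],
            tangent=geo["tangent"],
            length=geo["length"],
            radius=geo["radius"],
            speed=speed,
            down_node=down_node,
            out_edges=out_tables,
            inlet_edges=inlet,
            inlet_probs=pi,
        )

    def route(self, edge_idx: np.ndarray, overshoot: np.ndarray, rng: np.random.Generator):
        """Route spins that passed their edge's downstream end.

        Returns (new edge indices, new positions).  Spin count is
        conserved: terminal-node spins are re-injected at an inlet.
        """
        new_edge = np.empty(edge_idx.shape, dtype=np.int64)
        new_pos = np.empty((edge_idx.size, 3))
        for k, (e, s) in enumerate(zip(edge_idx, overshoot)):
            table = self.out_edges.get(int(self.down_node[e]))
            if table is not None:
                idxs, p = table
                ne = int(rng.choice(idxs, p=p))
                adv = min(max(s, 0.0), self.length[ne])
            else:
                ne = int(rng.choice(self.inlet_edges, p=self.inlet_probs))
                adv = 0.0
                self.n_reinjected += 1
            new_edge[k] = ne
            new_pos[k] = self.p_up[ne] + adv * self.tangent[ne]
        return new_edge, new_pos


@dataclass
class SpinEnsemble:
    """State of the random walkers.

    Positions are continuous (unwrapped) coordinates in µm; field maps
    are sampled periodically.  ``log_amp`` is the per-spin α (≤ 0),
    ``phase`` the accumulated ΔB phase φ_B, and ``grad_moment`` the
    per-spin accumulator q (µm) from which any gradient direction's
    phase is reconstructed at readout.
    """

    positions: np.ndarray  # (N,3) µm
    log_amp: np.ndarray  # (N,)
    phase: np.ndarray  # (N,) rad, ΔB part
    is_iv: np.ndarray  # (N,) bool
    current_edge: np.ndarray  # (N,) int, -1 for EV
    grad_moment: np.ndarray = field(default=None)  # (N,3) µm

    def __post_init__(self) -> None:
        if self.grad_moment is None:
            self.grad_moment = np.zeros_like(self.positions)

    @property
    def n(self) -> int:
        return len(self.log_amp)


def initialize_spins(
    n: int,
    maps: FieldMaps,
    mode: str = "full",
    seed: int | np.random.Generator = 0,
    router: FlowRouter | None = None,
) -> SpinEnsemble:
    """Place spins uniformly over the domain (``full``) or lumen (``asl``).

    ASL is emulated by initializing spins only inside the vascular
    space; ``full`` mode covers the whole box, with IV/EV membership
    read off the lumen mask.
    """
    if n < 1:
        raise ValidationError("n must be >= 1")
    if mode not in ("full", "asl"):
        raise ValidationError(f"unknown mode {mode!r}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    grid = maps.grid
    ext = grid.extent
    if mode == "full":
        pos = rng.uniform(0.0, 1.0, (n, 3)) * ext
        ix, iy, iz = grid.voxel_index(pos)
        iv = maps.lumen_mask[ix, iy, iz]
        edge = np.where(iv, maps.edge_label[ix, iy, iz], -1)
    else:
        lumen_vox = np.argwhere(maps.lumen_mask)
        if lumen_vox.size == 0:
            raise ValidationError("ASL mode requires a non-empty lumen")
        pick = rng.integers(0, len(lumen_vox), n)
        jitter = rng.uniform(0.0, 1.0, (n, 3))
        pos = (lumen_vox[pick] + jitter) * grid.spacing + np.asarray(grid.origin)
        iv = np.ones(n, dtype=bool)
        edge = maps.edge_label[tuple(lumen_vox[pick].T)]
    if router is not None:
        _snap_into_lumen(pos, iv, edge, router)
    return SpinEnsemble(
        positions=pos,
        log_amp=np.zeros(n),
        phase=np.zeros(n),
        is_iv=iv,
        current_edge=edge.astype(np.int64),
    )


def _snap_into_lumen(pos: np.ndarray, iv: np.ndarray, edge: np.ndarray, router: FlowRouter) -> None:
    """Pull IV spins sampled in boundary voxels onto their edge's cylinder.

    Lumen voxels only approximate the analytic tube; a spin seeded in the
    sliver outside it would have every proposal rejected, so it is
    projected radially/axially just inside instead (in place).
    """
    idx = np.flatnonzero(iv & (edge >= 0))
    if idx.size == 0:
        return
    e = edge[idx]
    rel = pos[idx] - router.p_up[e]
    s = np.einsum("ij,ij->i", rel, router.tangent[e])
    s_in = np.clip(s, 0.0, router.length[e])
    radial = rel - s[:, None] * router.tangent[e]
    d = np.linalg.norm(radial, axis=1)
    lim = 0.99 * router.radius[e]
    shrink = np.where(d > lim, lim / np.maximum(d, 1e-12), 1.0)
    pos[idx] = router.p_up[e] + s_in[:, None] * router.tangent[e] + shrink[:, None] * radial


# ---------------------------------------------------------------------------
# Motion kernel
# ---------------------------------------------------------------------------


def _move(
    ens: SpinEnsemble,
    maps: FieldMaps,
    router: FlowRouter | None,
    diffusivity: float,
    dt: float,
    rng: np.random.Generator,
) -> None:
    """One Δt of diffusion + advection with boundary rejection and routing."""
    n = ens.n
    sigma = np.sqrt(2.0 * diffusivity * dt)
    disp = rng.normal(0.0, sigma, (n, 3)) if sigma > 0 else np.zeros((n, 3))
    ext = maps.grid.extent

    ev = ~ens.is_iv
    if np.any(ev):
        new = ens.positions[ev] + disp[ev]
        if maps.lumen_mask.any():
            wrapped = np.mod(new, ext)
            ix, iy, iz = maps.grid.voxel_index(wrapped)
            blocked = maps.lumen_mask[ix, iy, iz]
            new[blocked] = ens.positions[ev][blocked]
        ens.positions[ev] = new

    if router is not None and np.any(ens.is_iv):
        iv = np.flatnonzero(ens.is_iv)
        e = ens.current_edge[iv]
        adv = (router.speed[e] * dt)[:, None] * router.tangent[e]
        new = ens.positions[iv] + disp[iv] + adv
        rel = new - router.p_up[e]
        s = np.einsum("ij,ij->i", rel, router.tangent[e])
        d2 = np.einsum("ij,ij->i", rel, rel) - s**2
        radial_ok = d2 <= router.radius[e] ** 2
        inside = radial_ok & (s >= 0.0) & (s <= router.length[e])
        passed = radial_ok & (s > router.length[e])
        accept = np.flatnonzero(inside)
        ens.positions[iv[accept]] = new[accept]
        routed = np.flatnonzero(passed)
        if routed.size:
            ne, np_ = router.route(e[routed], s[routed] - router.length[e[routed]], rng)
            ens.current_edge[iv[routed]] = ne
            ens.positions[iv[routed]] = np_
        # everything else (radial exit or upstream overshoot): rejected, keep position


def advect_routing(ensemble: SpinEnsemble, network: VascularNetwork, router: FlowRouter | None = None) -> SpinEnsemble:
    """Re-assign ``current_edge`` for IV spins past their edge's end.

    Convenience wrapper over :class:`FlowRouter` for spins whose axial
    coordinate exceeds their current edge's length.
    """
    if router is None:
        router = FlowRouter.from_network(network)
    rng = np.random.default_rng(0)
    iv = np.flatnonzero(ensemble.is_iv)
    e = ensemble.current_edge[iv]
    rel = ensemble.positions[iv] - router.p_up[e]
    s = np.einsum("ij,ij->i", rel, router.tangent[e])
    passed = np.flatnonzero(s > router.length[e])
    if passed.size:
        ne, np_ = router.route(e[passed], s[passed] - router.length[e[passed]], rng)
        ensemble.current_edge[iv[passed]] = ne
        ensemble.positions[iv[passed]] = np_
    return ensemble


def step(
    ensemble: SpinEnsemble,
    maps: FieldMaps,
    params: SequenceParams,
    step_index: int,
    router: FlowRouter | None = None,
    gradient_direction=None,
    diffusivity: float = DEFAULT_DIFFUSIVITY,
    rng: np.random.Generator | None = None,
) -> SpinEnsemble:
    """Advance the ensemble one Δt (single-direction reference path).

    Applies motion, T2 decay and phase accrual for step ``step_index``
    of the sequence; ``gradient_direction=None`` means G = 0.  The fast
    multi-direction path in :func:`run_sequence` is algebraically
    identical.
    """
    rng = rng if rng is not None else np.random.default_rng(0)
    d_sign, c_sign = step_schedule(params)
    if not 0 <= step_index < params.n_steps:
        raise ValidationError("step_index off the Δt lattice")
    _move(ensemble, maps, router, diffusivity, params.dt, rng)
    dt_s = params.dt * 1e-3
    wrapped = np.mod(ensemble.positions, maps.grid.extent)
    ix, iy, iz = maps.grid.voxel_index(wrapped)
    t2_s = maps.t2[ix, iy, iz]
    ensemble.log_amp -= dt_s / t2_s
    db = maps.delta_b[ix, iy, iz] if maps.delta_b is not None else 0.0
    ensemble.phase += d_sign[step_index] * params.gamma * dt_s * db
    if c_sign[step_index] != 0.0:
        x_c = 0.5 * maps.grid.extent
        if gradient_direction is not None:
            u = np.asarray(gradient_direction, dtype=float)
            proj_um = (ensemble.positions - x_c) @ u
            ensemble.phase += c_sign[step_index] * params.gamma * dt_s * params.g_amp * proj_um * 1e-6
        else:
            ensemble.grad_moment += c_sign[step_index] * (ensemble.positions - x_c)
    return ensemble


# ---------------------------------------------------------------------------
# Full sequence
# ---------------------------------------------------------------------------


@dataclass
class SignalTrace:
    """Readout of one simulated experiment."""

    times: np.ndarray  # ms
    s0: float  # |S0| at readout
    s_i: np.ndarray  # |S_i| per direction at readout
    directions: np.ndarray
    ratios: np.ndarray  # S_i / S0
    signal: np.ndarray | None = None  # (T, M+1) complex time series, S0 first
    n_spins: int = 0
    mode: str = "full"

    def save(self, path) -> None:
        """Persist the trace to HDF5."""
        import h5py

        with h5py.File(path, "w") as f:
            f.attrs["s0"] = self.s0
            f.attrs["n_spins"] = self.n_spins
            f.attrs["mode"] = self.mode
            f.create_dataset("times", data=self.times)
            f.create_dataset("s_i", data=self.s_i)
            f.create_dataset("directions", data=self.directions)
            f.create_dataset("ratios", data=self.ratios)
            if self.signal is not None:
                f.create_dataset("signal", data=self.signal)

    @classmethod
    def load(cls, path) -> "SignalTrace":
        import h5py

        with h5py.File(path, "r") as f:
            return cls(
                times=f["times"][:],
                s0=float(f.attrs["s0"]),
                s_i=f["s_i"][:],
                directions=f["directions"][:],
                ratios=f["ratios"][:],
                signal=f["signal"][:] if "signal" in f else None,
                n_spins=int(f.attrs["n_spins"]),
                mode=str(f.attrs["mode"]),
            )


def run_sequence(
    network: VascularNetwork | None,
    maps: FieldMaps,
    params: SequenceParams,
    mode: str = "full",
    seed: int | np.random.Generator = 0,
    n_spins: int = DEFAULT_N_SPINS,
    diffusivity: float = DEFAULT_DIFFUSIVITY,
    record_every: int | None = None,
) -> SignalTrace:
    """Simulate S0 and every gradient direction for one sample.

    Spin paths are identical across directions (common random numbers);
    set ``record_every`` to store the complex signal time series at that
    step stride.
    """
    if maps.t2 is None:
        raise ValidationError("field maps must include a T2 volume (run build_field_maps)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    router = FlowRouter.from_network(network) if network is not None and network.n_edges else None
    ens = initialize_spins(n_spins, maps, mode, rng, router)
    d_sign, c_sign = step_schedule(params)
    dt_s = params.dt * 1e-3
    x_c = 0.5 * maps.grid.extent
    dirs = params.directions
    scale = params.gamma * params.g_amp * dt_s * 1e-6  # rad per µm of signed position sum

    times, series = [], []
    has_db = maps.delta_b is not None
    for k in range(params.n_steps):
        _move(ens, maps, router, diffusivity, params.dt, rng)
        wrapped = np.mod(ens.positions, maps.grid.extent)
        ix, iy, iz = maps.grid.voxel_index(wrapped)
        ens.log_amp -= dt_s / maps.t2[ix, iy, iz]
        if has_db:
            ens.phase += d_sign[k] * params.gamma * dt_s * maps.delta_b[ix, iy, iz]
        if c_sign[k] != 0.0:
            ens.grad_moment += c_sign[k] * (ens.positions - x_c)
        if record_every and (k + 1) % record_every == 0:
            times.append((k + 1) * params.dt)
            E = np.exp(ens.log_amp + 1j * ens.phase)
            ph = scale * (ens.grad_moment @ dirs.T)
            row = np.empty(len(dirs) + 1, dtype=complex)
            row[0] = E.mean()
            row[1:] = (E[:, None] * np.exp(1j * ph)).mean(axis=0)
            series.append(row)

    E = np.exp(ens.log_amp + 1j * ens.phase)
    s0 = abs(E.mean())
    ph = scale * (ens.grad_moment @ dirs.T)
    s_i = np.abs((E[:, None] * np.exp(1j * ph)).mean(axis=0))
    return SignalTrace(
        times=np.asarray(times) if times else np.array([params.te]),
        s0=float(s0),
        s_i=s_i,
        directions=dirs,
        ratios=s_i / s0,
        signal=np.asarray(series) if series else None,
        n_spins=n_spins,
        mode=mode,
    )
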