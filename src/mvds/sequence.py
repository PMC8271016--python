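"""Pulsed-gradient spin-echo DWI sequence: timing, b-value algebra, directions.

The sequence is a single spin echo with two rectangular diffusion lobes
of duration δ separated by Δ, placed symmetrically about the 180° pulse
at TE/2 (lobe centers at TE/2 ∓ Δ/2), readout at TE.  The diffusion
weighting follows b = γ²G²δ²(Δ − δ/3) with γ the proton gyromagnetic
ratio.  Gradient directions are sampled on a spherical lattice controlled
by two separation angles Δθ₁ (polar) and Δθ₂ (azimuthal), with poles
emitted once and antipodal duplicates removed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .network import ValidationError

GAMMA_H = 2.675e8  # proton gyromagnetic ratio, rad s^-1 T^-1
DEFAULT_DT_MS = 0.05


def b_value(g_amp: float, delta_small: float, delta_big: float, gamma: float = GAMMA_H) -> float:
    """b (s/mm²) from gradient amplitude G (T/m) and timings (ms)."""
    if delta_small <= 0 or delta_big <= 0:
        raise ValidationError("delta_small and delta_big must be > 0")
    if delta_small > delta_big:
        raise ValidationError("delta_small must not exceed delta_big")
    d, D = delta_small * 1e-3, delta_big * 1e-3  # s
    b_si = gamma**2 * g_amp**2 * d**2 * (D - d / 3.0)  # s/m²
    return b_si * 1e-6  # s/mm²


def gradient_amplitude(b: float, delta_small: float, delta_big: float, gamma: float = GAMMA_H) -> float:
    """Gradient amplitude G (T/m) achieving diffusion weighting b (s/mm²)."""
    if b < 0:
        raise ValidationError("b must be >= 0")
    if delta_small <= 0 or delta_small > delta_big:
        raise ValidationError("require 0 < delta_small <= delta_big")
    d, D = delta_small * 1e-3, delta_big * 1e-3
    return float(np.sqrt(b * 1e6 / (gamma**2 * d**2 * (D - d / 3.0))))


def gradient_directions(dtheta1_deg: float = 30.0, dtheta2_deg: float = 30.0) -> np.ndarray:
    """Spherical-lattice gradient direction set.

    Polar angles θ ∈ {0, Δθ₁, …, 180°}, azimuths φ ∈ {0, Δθ₂, …,
    360° − Δθ₂}.  The poles appear once, and of each antipodal pair only
    the first-encountered member is kept (a spin-echo magnitude readout
    cannot distinguish u from −u).
    """
    for a in (dtheta1_deg, dtheta2_deg):
        if a <= 0 or abs(round(180.0 / a) - 180.0 / a) > 1e-9:
            raise ValidationError(f"separation angle {a} must divide 180")
    thetas = np.deg2rad(np.arange(0.0, 180.0 + 1e-9, dtheta1_deg))
    phis = np.deg2rad(np.arange(0.0, 360.0 - 1e-9, dtheta2_deg))
    out: list[np.ndarray] = []
    for th in thetas:
        if min(abs(th), abs(th - np.pi)) < 1e-12:
            cand = [np.array([0.0, 0.0, np.cos(th)])]
        else:
            cand = [
                np.array([np.sin(th) * np.cos(ph), np.sin(th) * np.sin(ph), np.cos(th)])
                for ph in phis
            ]
        for v in cand:
            if not any(abs(abs(v @ u) - 1.0) < 1e-9 for u in out):
                out.append(v)
    return np.array(out)


@dataclass(frozen=True)
class Timeline:
    """Discrete-time sequence events, all on the Δt lattice (ms)."""

    t_90: float
    lobe1: tuple[float, float]
    t_180: float
    lobe2: tuple[float, float]
    t_readout: float

    def events(self) -> list[float]:
        return [self.t_90, *self.lobe1, self.t_180, *self.lobe2, self.t_readout]


@dataclass
class SequenceParams:
    """Complete description of one pulsed-gradient spin-echo experiment."""

    b0: float = 3.0  # Tesla
    te: float = 16.0  # ms
    delta_small: float = 3.0  # ms, lobe duration δ
    delta_big: float = 6.0  # ms, lobe separation Δ
    b: float = 500.0  # s/mm²
    gamma: float = GAMMA_H
    dt: float = DEFAULT_DT_MS  # ms
    dtheta1_deg: float = 30.0
    dtheta2_deg: float = 30.0
    directions: np.ndarray | None = None
    b0_direction: tuple[float, float, float] = (0.0, 0.0, 1.0)

    def __post_init__(self) -> None:
        if self.delta_small > self.delta_big:
            raise ValidationError("δ must not exceed Δ")
        if self.delta_big + self.delta_small > self.te:
            raise ValidationError("δ + Δ must fit inside TE")
        if self.b < 0:
            raise ValidationError("b must be >= 0")
        if self.dt <= 0:
            raise ValidationError("dt must be > 0")
        if self.directions is None:
            self.directions = gradient_directions(self.dtheta1_deg, self.dtheta2_deg)
        self.directions = np.asarray(self.directions, dtype=float)
        norms = np.linalg.norm(self.directions, axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-9):
            raise ValidationError("gradient directions must be unit vectors")

    @property
    def g_amp(self) -> float:
        """Gradient amplitude (T/m) realizing the requested b-value."""
        return gradient_amplitude(self.b, self.delta_small, self.delta_big, self.gamma)

    @property
    def n_steps(self) -> int:
        return int(round(self.te / self.dt))


def _snap(t: float, dt: float, center: float) -> float:
    """Snap an event time onto the Δt lattice, rounding toward ``center``."""
    n = t / dt
    snapped = np.floor(n) if t > center else np.ceil(n)
    if abs(n - round(n)) < 1e-9:
        snapped = round(n)
    return float(snapped * dt)


def build_timeline(params: SequenceParams) -> Timeline:
    """Event times of the spin-echo DWI block.

    Lobes are centered at TE/2 ∓ Δ/2 (echo-symmetric about the 180°
    pulse); events are snapped to the Δt lattice toward the echo center
    so refocusing stays exact in discrete time.
    """
    te, dt = params.te, params.dt
    t180 = te / 2.0
    c1, c2 = t180 - params.delta_big / 2.0, t180 + params.delta_big / 2.0
    half = params.delta_small / 2.0
    lobe1 = (_snap(c1 - half, dt, t180), _snap(c1 + half, dt, t180))
    lobe2 = (_snap(c2 - half, dt, t180), _snap(c2 + half, dt, t180))
    if lobe1[0] < 0 or lobe2[1] > te:
        raise ValidationError("gradient lobes fall outside the 90°–readout window")
    if lobe1[1] > t180 or lobe2[0] < t180:
        raise ValidationError("gradient lobes overlap the 180° pulse")
    return Timeline(t_90=0.0, lobe1=lobe1, t_180=t180, lobe2=lobe2, t_readout=te)


def step_schedule(params: SequenceParams) -> tuple[np.ndarray, np.ndarray]:
    """Per-step refocusing sign d_n and signed lobe indicator c_n.

    Step n covers (n·Δt, (n+1)·Δt]; its midpoint decides which side of
    the 180° pulse it is on and whether a lobe is active.  c_n = d_n when
    a lobe is on during step n, else 0, so that the gradient phase of a
    static spin cancels exactly at the echo.
    """
    tl = build_timeline(params)
    n = params.n_steps
    mid = (np.arange(n) + 0.5) * params.dt
    d = np.where(mid < tl.t_180, 1.0, -1.0)
    on = ((mid > tl.lobe1[0]) & (mid < tl.lobe1[1])) | ((mid > tl.lobe2[0]) & (mid < tl.lobe2[1]))
    return d, np.where(on, d, 0.0)
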