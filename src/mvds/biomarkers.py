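"""Direction-wise signal-loss biomarkers ψ and φ, noise model, IVIM signal.

Given the set of direction-wise signal ratios R = {r_i = S_i/S_0}, two
scalar markers summarize orientation anisotropy of the microvascular
bed: ψ = max(R) − min(R), the spread of signal loss across gradient
directions, and φ = 1 − max(R), the minimal intravoxel signal-loss
ratio.  Isotropic (healthy-like) beds give small ψ; radially organized
(post-occlusion-like) beds lose signal preferentially for in-plane
gradients and give larger ψ and φ.
"""

from __future__ import annotations

import numpy as np

from .network import ValidationError


def psi(ratios) -> float:
    """Spread of direction-wise signal loss: max(R) − min(R)."""
    r = np.asarray(ratios, dtype=float).ravel()
    if r.size < 2:
        raise ValidationError("psi needs at least 2 direction ratios")
    return float(r.max() - r.min())


def phi(ratios) -> float:
    """Minimal intravoxel signal-loss ratio: 1 − max(R)."""
    r = np.asarray(ratios, dtype=float).ravel()
    if r.size < 1:
        raise ValidationError("phi needs at least 1 direction ratio")
    return float(1.0 - r.max())


def add_noise(signal, snr: float, s_ref: float, seed: int | np.random.Generator = 0):
    """Complex Gaussian measurement noise; returns the Rician magnitude.

    Independent zero-mean Gaussians of σ = s_ref/snr are added to the
    real and imaginary channels of each readout; the returned magnitude
    is Rician-distributed.  ``s_ref`` is conventionally the noiseless
    S0.
    """
    if snr <= 0:
        raise ValidationError("snr must be > 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    s = np.asarray(signal, dtype=complex)
    sigma = s_ref / snr
    noisy = s + rng.normal(0.0, sigma, s.shape) + 1j * rng.normal(0.0, sigma, s.shape)
    out = np.abs(noisy)
    return out if out.ndim else float(out)


def ivim_model_signal(s0: float, f: float, b, D: float, D_star: float):
    """Two-compartment IVIM signal S = S0·[f·e^{−bD*} + (1−f)·e^{−bD}].

    ``f`` is the vascular volume fraction, ``D`` the tissue apparent
    diffusion coefficient and ``D_star`` the perfusion pseudo-diffusion
    coefficient (both in mm²/s when b is in s/mm²).
    """
    if not 0.0 <= f <= 1.0:
        raise ValidationError("f must lie in [0, 1]")
    b = np.asarray(b, dtype=float)
    out = s0 * (f * np.exp(-b * D_star) + (1.0 - f) * np.exp(-b * D))
    return out if out.ndim else float(out)
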