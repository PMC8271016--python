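# Methods

`mvds` simulates the pulsed-gradient spin-echo (PGSE) diffusion MRI
response of cerebral microvascular networks by Monte-Carlo spin
dynamics, and derives two scalar biomarkers of capillary orientation
anisotropy from multi-directional readouts. This note records the model,
its assumptions, the tunable parameters, and the design choices made
where more than one reasonable option existed.

## Model overview

A microvascular bed is a geometric graph: nodes carry centerline
positions (µm) and local radii (µm); edges are straight segments with a
vessel class (artery / vein / capillary), a flow orientation, a blood
speed (mm/s), an oxygen partial pressure PO2 (mmHg), a hemoglobin
saturation SO2 and a hematocrit. Coordinates are right-handed, in µm,
z increasing with cortical depth, origin at the top corner of the
domain; depth of a segment is the |z| of its midpoint (a per-edge
convention — the alternative per-node convention differs negligibly for
30–60 µm segments).

The pipeline is:

1. **Physiology.** Speed and PO2 are predicted per segment from
   (radius, class, depth) by two random-forest regressors (100 trees,
   max depth 10, min samples to split 2, bootstrap, MSE splits).
   Vessels are classed capillary at mean radius ≤ 3 µm, otherwise
   artery or vein with probability 1/2 each. PO2 → SO2 uses the Hill
   equation with C57BL/6 mouse coefficients h = 2.59, P50 = 40.2 mmHg.
   Hematocrit is 0.44 in arterioles/venules and 0.33 in capillaries.
2. **Field maps.** The network is rasterized onto an isotropic voxel
   grid (default 2 µm): a voxel is lumen iff its center lies within one
   radius of a segment's centerline (capsule semantics; spherical caps
   join segments smoothly at nodes), ties to the smaller edge index.
   The susceptibility shift is χ = Δχ_do·Hct·(1 − SO2) inside the lumen
   (Δχ_do default 4π·0.264 ppm per unit hematocrit, configurable), and
   ΔB = B0·IFT[D(k)·FT[χ]] with the Lorentz-corrected dipole kernel
   D(k) = 1/3 − (k·b̂)²/|k|², D(0) := 0, periodic boundaries. The
   closed-form check: an infinite cylinder's interior field is
   Δχ·B0/3 parallel to B0 and −Δχ·B0/6 perpendicular. T2 maps (s):
   tissue [1.74·B0 + 7.77]⁻¹, vessel
   [12.67·B0²·(1−SO2)² + 2.74·B0 − 0.6]⁻¹. The vessel expression is
   non-positive below B0 ≈ 0.22 T; such B0 are rejected, never clamped.
3. **Sequence.** One spin echo: 90° at t = 0, 180° at TE/2, readout at
   TE; rectangular diffusion lobes of duration δ centered at
   TE/2 ∓ Δ/2 (echo-symmetric placement — the alternative of abutting
   the RF pulses is not distinguishable from the available description;
   symmetry keeps discrete-time refocusing exact). b = γ²G²δ²(Δ − δ/3)
   with γ = 2.675×10⁸ rad s⁻¹ T⁻¹. Gradient directions sample a
   spherical lattice with polar/azimuthal separations Δθ₁, Δθ₂ (poles
   once, antipodal duplicates removed; 31 directions at 30°/30°).
4. **Spin dynamics.** N spins (default 5×10⁴ at desk scale; 10⁶
   reproduces full scale) random-walk with Δt = 0.05 ms and isotropic
   diffusivity D = 0.8 µm²/ms. Intravascular (IV) spins additionally
   advect at their segment's plug-flow speed along its flow-oriented
   tangent; a spin reaching a segment's downstream node continues onto
   an outgoing edge with probability ∝ volumetric flow (speed·πr²), and
   at a terminal node is re-injected at a flow-weighted inlet with
   amplitude and phase preserved (spin count is conserved). Wall
   exchange is neglected: a proposed crossing of the lumen boundary (in
   either direction) is rejected and the spin keeps its position for
   that step. Per step, log-amplitude decays by Δt/T2 at the spin's
   voxel and phase advances by d·γ·Δt·[ΔB(x) + G·(u·(x − x_c))], d = +1
   before the 180° pulse, −1 after, gradient active only during a lobe.
   The voxel signal is the magnitude of the ensemble-averaged complex
   amplitude (aggregating before the magnitude is the only reading that
   produces diffusion attenuation; a per-spin magnitude would discard
   all phase dispersion).
5. **Biomarkers.** With R = {rᵢ = Sᵢ/S₀} over gradient directions,
   ψ = max(R) − min(R) and φ = 1 − max(R). ASL is emulated by seeding
   spins only inside the lumen; the full-voxel mode seeds uniformly
   over the box. Optional measurement noise adds independent
   zero-mean Gaussians of σ = S₀/SNR to the real and imaginary readout
   channels, giving Rician magnitudes.

### Numerical choices

* **Common random numbers / shared trajectories.** Spin paths do not
  depend on the gradient direction, so one walk per (sample, mode)
  serves every direction: the engine accumulates a per-spin vector
  q = Σₙ cₙ(xₙ − x_c) over lobe steps (cₙ the signed lobe indicator)
  and reconstructs each direction's phase as γ·G·Δt·u·q at readout.
  This is algebraically identical to re-running the sequence per
  direction with the same seed and ~30× faster. A reference
  single-direction `step()` path exists and is tested for agreement.
* **Unwrapped coordinates.** Extravascular spins move in continuous
  coordinates; field maps are sampled periodically (position mod box).
  Gradient phase uses the unwrapped position, which is the correct
  physics of an effectively infinite medium — wrapping the phase
  coordinate would inject artificial dephasing for spins crossing the
  boundary during a lobe.
* **Discrete-time refocusing.** Sequence events snap to the Δt lattice
  toward the echo center; each step's midpoint decides its refocusing
  sign and lobe membership, so the number of +/− steps (and signed lobe
  steps) balances exactly and a static spin's phase cancels at TE to
  machine precision. The residual discretization bias of the discrete
  b-value relative to γ²G²δ²(Δ−δ/3) is ~6×10⁻⁵ at the default
  timings — far below Monte-Carlo error.
* **Boundary rejection and seeding.** Lumen voxels only approximate the
  analytic tube, so IV spins seeded in the sliver outside their edge's
  cylinder are projected just inside it at initialization; otherwise
  every subsequent proposal would be rejected and the spin would
  artificially freeze.
* **Degenerate inputs.** Zero-length edges are rejected rather than
  contracted (keeps tangents well-defined); self-loops, dangling edge
  endpoints, non-finite attributes and out-of-box nodes all raise
  validation errors; a grid coarser than the smallest radius warns.

## Synthetic data

Real post-stroke angiograms are not redistributable, so two generators
stand in for them; both are first-class, tested code.

**Capillary beds.** Straight 2-node segments, radii uniform in 2–4 µm,
independent ±1 flow orientation per segment, midpoints uniform in a
200×200×200 µm box, lengths uniform in 30–60 µm (box and lengths are
package choices giving capillary-like densities — a 150–200 segment bed
occupies ~1–3% of the box, consistent with the few-percent vascular
volume fraction of cortical tissue). *Random* beds draw orientations
uniformly on the sphere (healthy-like isotropy). *Radial* beds point
each tangent along the in-plane radial direction from a central
vertical axis, with wrapped-normal jitter of σ = 15° by default on the
in-plane angle (the post-occlusion reorganization these beds emulate is
radial in the lateral plane). Cohorts default to 30 samples per group,
with per-sample seeds spawned from a master seed and a JSON manifest.

What these beds do **not** model: branching topology, longitudinal
remodeling dynamics, vessel tortuosity, and the large penetrating
vessels of real angiograms. Passing the cohort-discrimination tests
therefore shows that the *simulator* resolves orientation anisotropy
under the stated geometry, not that real post-stroke tissue would yield
the same effect sizes.

**Physiology table.** The regression targets are drawn from a
documented generative model (see `physiology.PHYSIO_GENERATOR`): PO2
falls linearly with depth and from artery → capillary → vein
(intercepts 90/60/45 mmHg), speed grows as radius^1.2 with
class-specific coefficients (≈1.1 mm/s for a 3 µm capillary, ≈5 mm/s
for a 10 µm arteriole), plus additive PO2 noise (σ = 4 mmHg) and
relative speed noise (10%). These ranges are assumptions chosen to be
physiologically plausible for mouse cortex; the forest fitted on a
low-noise table recovers the generator (held-out R² > 0.7, asserted).
A CSV loader accepts user-supplied measurement tables with the same
schema (`radius_um, type, depth_um, po2_mmHg, speed_mm_s`).

## Experiments and statistics

* **Effect-size sweep**: Mann–Whitney U (two-sided) between the
  cohorts' per-sample ψ at each grid point of (B0, TE, δ, b) × {ASL,
  full}. Exact enumeration for pooled n ≤ 20, tie-corrected normal
  approximation above.
* **Cohort comparison**: Friedman rank test across conditions (one
  synthetic network = one subject), tie-corrected, with pairwise
  Wilcoxon signed-rank post-hocs under Holm step-down adjustment (the
  post-hoc procedure is a package choice; it is the standard
  conservative follow-up).
* **SNR robustness**: the same φ statistics after Rician readout noise
  at SNR ∈ {15, 25, 50}, against a noiseless reference column.

At the desk scale used in the test suite (10 samples/group,
150 segments, 2×10⁴ spins), ASL ψ separates radial from random beds by
roughly a factor of four to five (≈0.35–0.5 vs ≈0.08–0.1 across
seeds), while the full-voxel contrast is more than an order of
magnitude smaller (≈0.01, sign-unstable) — ASL is what makes
the orientation signature usable, because extravascular water dominates
the full-voxel signal. Both contrasts can saturate the exact
Mann–Whitney test's smallest attainable p (2/C(20,10)); the meaningful
ASL advantage at this scale is the effect size, not the p-value floor.
φ is *smaller* for radial beds: the gradient perpendicular to the
lateral plane sees almost no perfusion-driven loss, raising max(R).

## OCT stack fusion

Depth-dependent angiogram stacks are fused as Σ wᵢDᵢ with wᵢ the
softmax (temperature 1) of each stack's mean local entropy: per slice,
normalize to [0, 1], filter with an 18-kernel Gabor bank (orientations
{0, π/6, π/3, π/2, 2π/3, π}, phase offsets {2.5, 5, 7.5} rad, carrier
frequency 0.01 cycles/px — the normalized-frequency reading of the
wavelength knob; both are configurable), aggregate the 18 responses by
mean absolute value, then average 15×15-window Shannon entropy (256
gray levels) over pixels and slices. The Gaussian envelope of the
Gabor kernels is fixed at σ = 3 px: at a 0.01 cycles/px carrier the
bandwidth-derived envelope would span hundreds of pixels and make
filtering intractable without changing the ranking behavior. Known
limitation: for sparse near-binary line images, heavier blur can
*raise* window entropy (smearing adds gray levels), so entropy weights
track texture richness, not sharpness per se; the guaranteed behaviors
are the tested ones (identical stacks → identity with equal weights;
constant stacks get the smallest weight; permutation equivariance).

## Problem sizes and limitations

Defaults in the test suite and the acceptance script are desk-scale
package choices: 5×10⁴ spins for free-diffusion oracles, 2×10⁴ for
cohort studies (10 samples/group, 150 segments), 300 spins and
5-sample cohorts for the 200-replicate null calibration. Full-scale
settings (10⁶ spins, 30 samples/group) are plain parameters.

Not modeled (out of scope by design): T1 relaxation, ASL labeling
kinetics and transit delays, vessel-wall permeability, restricted or
non-Gaussian extravascular diffusion, Poiseuille velocity profiles
(plug flow per segment), oxygen-transport PDEs (physiology is
regression-based), slice selection / EPI readout / eddy currents, and
segmentation or skeletonization of raw angiograms (graphs are inputs).
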