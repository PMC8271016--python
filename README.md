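# mvds — Monte-Carlo ASL/DWI simulation of cerebral microvascular beds

Micro-occlusions of single cortical vessels (microstrokes) are too
small to see directly with clinical MRI, but the capillary bed that
regrows around an infarct is not random: it reorganizes radially in the
lateral plane around the lesion. `mvds` is a simulation toolkit for
asking whether that geometric signature is visible in diffusion-weighted
MRI. It combines:

* a graph model of microvascular networks (centerline nodes with radii;
  segments with vessel class, flow, PO2/SO2, hematocrit);
* random-forest regression of blood speed and PO2 from segment geometry,
  Hill-equation oxygen saturation, and class-based hematocrit;
* voxelized field maps: deoxyhemoglobin susceptibility
  χ = Δχ_do·Hct·(1−SO2), the dipole-kernel field perturbation
  ΔB = B0·IFT[(1/3 − k_z'²/|k|²)·FT[χ]], and B0/SO2-dependent T2;
* a Monte-Carlo spin engine (diffusion D = 0.8 µm²/ms, plug-flow
  advection with flow-weighted routing at bifurcations, T2 decay, phase
  accrual with spin-echo refocusing) for a pulsed-gradient spin-echo
  sequence with b = γ²G²δ²(Δ − δ/3) and a spherical lattice of gradient
  directions;
* the orientation biomarkers computed from direction-wise ratios
  R = {Sᵢ/S₀}: the spread **ψ = max(R) − min(R)** and the minimal
  signal-loss ratio **φ = 1 − max(R)**;
* synthetic capillary-bed cohorts (randomly vs radially oriented),
  nonparametric statistics (exact Mann–Whitney, Friedman,
  Wilcoxon–Holm post-hocs), Rician readout noise, and entropy-weighted
  fusion of depth-dependent angiogram stacks.

It is aimed at researchers designing perfusion-sensitive diffusion
protocols (ASL + multi-directional IVIM) and at anyone who needs a
transparent, tested spin-dynamics sandbox for vascular geometries.
Everything runs from synthetic inputs; user-supplied networks (JSON or
GraphML) and physiology tables (CSV) drop into the same pipeline.

See `docs/methods.md` for the model, its assumptions and limitations.

## Worked example

```python
import numpy as np
from mvds.beds import generate_radial_bed, generate_random_bed
from mvds.experiments import default_forest, prepare_sample, cohort_biomarkers
from mvds.sequence import SequenceParams
from mvds.stats import mann_whitney_u

forest = default_forest(seed=0)          # physiology regressors
params = SequenceParams(b0=3.0, te=16.0, delta_small=3.0, delta_big=6.0,
                        b=500.0, dtheta1_deg=30.0, dtheta2_deg=30.0)

rand = [prepare_sample(generate_random_bed(150, seed=s), forest) for s in range(5)]
radial = [prepare_sample(generate_radial_bed(150, seed=s), forest) for s in range(5)]

t_rand = cohort_biomarkers(rand, params, mode="asl", seed=1, n_spins=20_000)
t_rad = cohort_biomarkers(radial, params, mode="asl", seed=2, n_spins=20_000)
u, p = mann_whitney_u(t_rand["psi"], t_rad["psi"])
print(f"psi random {t_rand['psi'].mean():.3f}  radial {t_rad['psi'].mean():.3f}  p={p:.4f}")
print(f"phi random {t_rand['phi'].mean():.3f}  radial {t_rad['phi'].mean():.3f}")
```

prints

```
psi random 0.078  radial 0.351  p=0.0079
phi random 0.674  radial 0.498
```

Read: with ASL (spins seeded only in the vessels, B0 = 3 T, TE = 16 ms,
b = 500 s/mm², 31 gradient directions), the spread of signal loss
across directions ψ is ~5× larger for radially organized beds than for
isotropic ones — the orientation signature — and the two 5-sample
cohorts already separate at the smallest p an exact rank test can give
for 5 vs 5. The minimal-loss ratio φ *drops* after radial
reorganization because the gradient perpendicular to the lateral plane
sees almost no perfusion-driven loss. Without ASL (`mode="full"`) the
extravascular water dilutes the contrast by an order of magnitude.

The same pipeline is scriptable from the shell:

```bash
mvds synth-beds --n 30 --seed 1 --out beds/
mvds run --network beds/radial_000.json --mode asl --b0 3 --b 500 --out trace.json
mvds sweep --n-per-group 10 --seed 1 --out sweep.csv
mvds robustness --n-per-group 10 --seed 1 --out robust
mvds fuse D1.tif D2.tif D3.tif -o fused.tif
```

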