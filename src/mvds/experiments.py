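"""Experiment orchestration: full pipeline runs and parameter sweeps.

Three experiment families are reproduced on synthetic cohorts:

* **effect-size sweep** — ψ computed per sample for randomly- vs
  radially-oriented beds over a grid of (B0, TE, δ, b), with and
  without ASL, Mann–Whitney p per grid point;
* **cohort comparison** — φ per sample across the two bed conditions,
  Friedman test plus Wilcoxon/Holm post-hocs (the stand-in for a
  longitudinal healthy-vs-lesion comparison when real angiograms are
  supplied);
* **SNR robustness** — the same φ statistics after Rician readout noise
  at several SNR levels, against a noiseless reference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import biomarkers as bm
from .beds import generate_cohorts
from .engine import DEFAULT_N_SPINS, run_sequence
from .fields import (
    DEFAULT_CHI_DO_PPM,
    VoxelGrid,
    dipole_convolve,
    hematocrit_map,
    rasterize_network,
    susceptibility_map,
    t2_field,
)
from .network import VascularNetwork
from .physiology import (
    PhysioConstants,
    PhysioForest,
    assign_hematocrit,
    assign_so2,
    fit_physio_forest,
    generate_physio_training_table,
    predict_physiology,
)
from .sequence import SequenceParams
from .stats import friedman_test, mann_whitney_u, posthoc_pairwise


def load_experiment_config(path) -> dict:
    """Read a YAML sweep/robustness configuration.

    Recognized keys mirror the keyword arguments of
    :func:`run_effect_size_sweep` and :func:`run_snr_robustness`
    (``b0_grid``, ``te_grid``, ``delta_grid``, ``b_grid``, ``modes``,
    ``snr_levels``, ``dtheta_deg``, ``n_spins``, ``seed``, ...).
    """
    import yaml

    with open(path) as f:
        cfg = yaml.safe_load(f)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: expected a mapping at the top level")
    return cfg


def default_forest(seed: int = 0, n_records: int = 1000) -> PhysioForest:
    """Physiology forest fitted on the synthetic training table."""
    table = generate_physio_training_table(n_records, seed=seed)
    return fit_physio_forest(table, seed=seed)


def prepare_network(
    network: VascularNetwork,
    forest: PhysioForest,
    constants: PhysioConstants = PhysioConstants(),
) -> VascularNetwork:
    """Populate physiology (speed, PO2, SO2, Hct) on a typed network."""
    predict_physiology(forest, network)
    assign_so2(network, constants)
    assign_hematocrit(network, constants)
    return network


@dataclass
class PreparedSample:
    """Rasterized sample with B0-independent maps cached."""

    network: VascularNetwork
    maps: object  # FieldMaps
    chi: np.ndarray

    def with_field(self, b0: float, b0_direction=(0.0, 0.0, 1.0)) -> "PreparedSample":
        self.maps.delta_b = dipole_convolve(self.chi, b0_direction, b0)
        self.maps.t2 = t2_field(self.maps.lumen_mask, self.maps.so2_map, b0)
        return self


def prepare_sample(
    network: VascularNetwork,
    forest: PhysioForest,
    spacing: float = 2.0,
    chi_do_ppm: float = DEFAULT_CHI_DO_PPM,
    constants: PhysioConstants = PhysioConstants(),
) -> PreparedSample:
    prepare_network(network, forest, constants)
    grid = VoxelGrid.for_box(network.bounding_box, spacing)
    maps = rasterize_network(network, grid)
    hct = hematocrit_map(network, maps)
    chi = susceptibility_map(maps.lumen_mask, maps.so2_map, hct, chi_do_ppm)
    return PreparedSample(network=network, maps=maps, chi=chi)


def cohort_biomarkers(
    samples: list[PreparedSample],
    params: SequenceParams,
    mode: str,
    seed: int,
    n_spins: int = DEFAULT_N_SPINS,
) -> pd.DataFrame:
    """Simulate every sample at ``params`` and tabulate ψ, φ and ratios."""
    ss = np.random.SeedSequence(seed).spawn(len(samples))
    rows = []
    for i, (sample, child) in enumerate(zip(samples, ss)):
        sample.with_field(params.b0, params.b0_direction)
        trace = run_sequence(
            sample.network, sample.maps, params, mode=mode,
            seed=np.random.default_rng(child), n_spins=n_spins,
        )
        rows.append(
            {
                "sample": i,
                "mode": mode,
                "b0": params.b0,
                "te": params.te,
                "delta": params.delta_small,
                "Delta": params.delta_big,
                "b": params.b,
                "s0": trace.s0,
                "psi": bm.psi(trace.ratios),
                "phi": bm.phi(trace.ratios),
                "ratios": trace.ratios,
            }
        )
    return pd.DataFrame(rows)


def ratios_long(table: pd.DataFrame) -> pd.DataFrame:
    """Expand a biomarker table to one row per (sample, direction) ratio."""
    rows = []
    for _, r in table.iterrows():
        for j, ratio in enumerate(np.asarray(r["ratios"])):
            rows.append(
                {
                    "sample": r["sample"], "mode": r["mode"], "b0": r["b0"], "te": r["te"],
                    "delta": r["delta"], "b": r["b"], "direction": j, "ratio": float(ratio),
                }
            )
    return pd.DataFrame(rows)


def run_effect_size_sweep(
    random_samples: list[PreparedSample],
    radial_samples: list[PreparedSample],
    b0_grid=(3.0, 7.0),
    te_grid=(16.0,),
    delta_grid=(3.0,),
    b_grid=(500.0,),
    delta_big: float = 6.0,
    modes=("asl", "full"),
    dtheta_deg: float = 30.0,
    seed: int = 0,
    n_spins: int = DEFAULT_N_SPINS,
) -> pd.DataFrame:
    """Mann–Whitney p on ψ between the two cohorts per grid point."""
    rows = []
    for mode in modes:
        for b0 in b0_grid:
            for te in te_grid:
                for delta in delta_grid:
                    for b in b_grid:
                        params = SequenceParams(
                            b0=b0, te=te, delta_small=delta, delta_big=delta_big, b=b,
                            dtheta1_deg=dtheta_deg, dtheta2_deg=dtheta_deg,
                        )
                        t_rand = cohort_biomarkers(random_samples, params, mode, seed, n_spins)
                        t_rad = cohort_biomarkers(radial_samples, params, mode, seed + 1, n_spins)
                        u, p = mann_whitney_u(t_rand["psi"], t_rad["psi"])
                        rows.append(
                            {
                                "mode": mode, "b0": b0, "te": te, "delta": delta, "b": b,
                                "u_stat": u, "p_value": p,
                                "psi_random_mean": t_rand["psi"].mean(),
                                "psi_radial_mean": t_rad["psi"].mean(),
                            }
                        )
    return pd.DataFrame(rows)


def run_snr_robustness(
    random_samples: list[PreparedSample],
    radial_samples: list[PreparedSample],
    snr_levels=(15.0, 25.0, 50.0),
    b0_grid=(3.0, 7.0),
    b: float = 500.0,
    te: float = 16.0,
    delta_small: float = 3.0,
    delta_big: float = 6.0,
    dtheta_deg: float = 30.0,
    seed: int = 0,
    n_spins: int = DEFAULT_N_SPINS,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """φ per sample and condition at each SNR, plus Friedman/post-hoc stats.

    Returns ``(phi_table, stats_table)``; the φ table includes a
    noiseless reference column (``snr = inf``).
    """
    phi_rows, stat_rows = [], []
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    for b0 in b0_grid:
        params = SequenceParams(
            b0=b0, te=te, delta_small=delta_small, delta_big=delta_big, b=b,
            dtheta1_deg=dtheta_deg, dtheta2_deg=dtheta_deg,
        )
        tabs = {
            "random": cohort_biomarkers(random_samples, params, "asl", seed, n_spins),
            "radial": cohort_biomarkers(radial_samples, params, "asl", seed + 1, n_spins),
        }
        for snr in (np.inf, *snr_levels):
            phis = {}
            for group, tab in tabs.items():
                vals = []
                for _, row in tab.iterrows():
                    s_i = row["ratios"] * row["s0"]
                    if np.isinf(snr):
                        ratios = row["ratios"]
                    else:
                        noisy_i = bm.add_noise(s_i.astype(complex), snr, row["s0"], rng)
                        noisy_0 = bm.add_noise(complex(row["s0"]), snr, row["s0"], rng)
                        ratios = noisy_i / noisy_0
                    vals.append(bm.phi(ratios))
                phis[group] = vals
                for samp, v in enumerate(vals):
                    phi_rows.append({"b0": b0, "snr": snr, "group": group, "sample": samp, "phi": v})
            blocks = np.array([phis["random"], phis["radial"]])
            chi2, p = friedman_test(blocks)
            post = posthoc_pairwise(blocks)
            stat_rows.append(
                {
                    "b0": b0, "snr": snr, "friedman_chi2": chi2, "friedman_p": p,
                    "posthoc_p_adj": post[0][2],
                    "phi_random_mean": float(np.mean(phis["random"])),
                    "phi_radial_mean": float(np.mean(phis["radial"])),
                }
            )
    return pd.DataFrame(phi_rows), pd.DataFrame(stat_rows)


def build_synthetic_study(
    n_per_group: int = 10,
    n_segments: int = 150,
    seed: int = 0,
    spacing: float = 2.0,
    box=(200.0, 200.0, 200.0),
) -> tuple[list[PreparedSample], list[PreparedSample]]:
    """Generate and fully prepare the two synthetic cohorts."""
    forest = default_forest(seed)
    random_beds, radial_beds = generate_cohorts(n_per_group, n_segments, box, seed=seed)
    rand = [prepare_sample(b, forest, spacing) for b in random_beds]
    radial = [prepare_sample(b, forest, spacing) for b in radial_beds]
    return rand, radial
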