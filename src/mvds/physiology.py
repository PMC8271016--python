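"""Per-segment physiology: flow speed and PO2 regression, SO2, hematocrit.

Blood speed and oxygen partial pressure are predicted per vessel segment
from (radius, type, depth) with random-forest regressors, mirroring an
approach trained on in-vivo two-photon measurements in mouse cortex.
Because that measurement table is not redistributable, a documented
synthetic generative model produces training tables with the same schema
and the physiologically expected trends (PO2 falling with depth and from
artery to capillary to vein; speed rising with radius); a loader accepts
user-supplied CSV tables of the same schema.

PO2 is converted to hemoglobin saturation with the Hill equation using
C57BL/6 mouse coefficients (h = 2.59, P50 = 40.2 mmHg), and hematocrit
is assigned by vessel class (0.44 in arterioles/venules, 0.33 in
capillaries).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor

from .network import ValidationError, VascularNetwork, VesselType, segment_geometry

CSV_COLUMNS = ["radius_um", "type", "depth_um", "po2_mmHg", "speed_mm_s"]

_TYPE_ORDER = [VesselType.ARTERY, VesselType.CAPILLARY, VesselType.VEIN]


@dataclass(frozen=True)
class PhysioConstants:
    """Hill-equation and hematocrit constants (C57BL/6 mouse)."""

    hill_h: float = 2.59
    hill_p50: float = 40.2  # mmHg
    hct_large: float = 0.44  # arterioles and venules
    hct_capillary: float = 0.33

    def __post_init__(self) -> None:
        for f in ("hill_h", "hill_p50", "hct_large", "hct_capillary"):
            if getattr(self, f) <= 0:
                raise ValidationError(f"{f} must be positive")


# ---------------------------------------------------------------------------
# Synthetic physiology training table
# ---------------------------------------------------------------------------

# Generative model (documented so that parameter recovery is testable):
#   PO2(type, depth)  = p0[type] - slope[type] * depth + N(0, po2_noise)
#   speed(type, r)    = k[type] * r^1.2 * (1 + N(0, speed_noise))
# with depth in µm, radius in µm, PO2 in mmHg, speed in mm/s.
PHYSIO_GENERATOR = {
    "po2_intercept": {"artery": 90.0, "capillary": 60.0, "vein": 45.0},  # mmHg
    "po2_depth_slope": {"artery": 0.040, "capillary": 0.030, "vein": 0.020},  # mmHg/µm
    "speed_coeff": {"artery": 0.35, "capillary": 0.30, "vein": 0.25},  # mm/s per µm^1.2
    "speed_radius_exp": 1.2,
    "po2_floor": 5.0,  # mmHg
    "depth_range": (0.0, 600.0),  # µm
    "radius_range": {"artery": (3.0, 30.0), "capillary": (2.0, 3.0), "vein": (3.0, 30.0)},
}


def physio_generator_mean(radius, vessel_type, depth) -> tuple[np.ndarray, np.ndarray]:
    """Noise-free (PO2, speed) of the synthetic generative model."""
    radius = np.asarray(radius, dtype=float)
    depth = np.asarray(depth, dtype=float)
    t = vessel_type.value if isinstance(vessel_type, VesselType) else str(vessel_type)
    g = PHYSIO_GENERATOR
    po2 = np.maximum(g["po2_intercept"][t] - g["po2_depth_slope"][t] * depth, g["po2_floor"])
    speed = g["speed_coeff"][t] * radius ** g["speed_radius_exp"]
    return po2, speed


def generate_physio_training_table(
    n: int = 300,
    po2_noise: float = 4.0,
    speed_noise: float = 0.10,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Synthetic stand-in for an in-vivo PO2/flow measurement table.

    Returns a DataFrame with columns ``radius_um, type, depth_um,
    po2_mmHg, speed_mm_s``.  ``po2_noise`` is additive Gaussian noise in
    mmHg; ``speed_noise`` is multiplicative relative noise.
    """
    if n < 50:
        raise ValidationError("need at least 50 records for a meaningful table")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    g = PHYSIO_GENERATOR
    types = rng.choice(["artery", "capillary", "vein"], n, p=[0.25, 0.5, 0.25])
    depth = rng.uniform(*g["depth_range"], n)
    radius = np.array([rng.uniform(*g["radius_range"][t]) for t in types])
    rows = []
    for i in range(n):
        po2_mu, v_mu = physio_generator_mean(radius[i], types[i], depth[i])
        po2 = max(float(po2_mu) + rng.normal(0.0, po2_noise), 0.0)
        speed = max(float(v_mu) * (1.0 + rng.normal(0.0, speed_noise)), 0.0)
        rows.append((radius[i], types[i], depth[i], po2, speed))
    return pd.DataFrame(rows, columns=CSV_COLUMNS)


def load_physio_table(path: str | Path) -> pd.DataFrame:
    """Load a user-supplied physiology CSV with the documented schema."""
    df = pd.read_csv(path)
    missing = set(CSV_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(f"physiology table missing columns {sorted(missing)}")
    return df[CSV_COLUMNS]


# ---------------------------------------------------------------------------
# Random-forest regression
# ---------------------------------------------------------------------------


def _features(radius, types, depth) -> np.ndarray:
    radius = np.asarray(radius, dtype=float)
    depth = np.asarray(depth, dtype=float)
    onehot = np.zeros((radius.size, len(_TYPE_ORDER)))
    tvals = [t.value if isinstance(t, VesselType) else str(t) for t in np.atleast_1d(types)]
    for j, vt in enumerate(_TYPE_ORDER):
        onehot[:, j] = [t == vt.value for t in tvals]
    return np.column_stack([radius, onehot, depth])


@dataclass
class PhysioForest:
    """Pair of fitted random forests predicting PO2 (mmHg) and speed (mm/s)."""

    po2_model: RandomForestRegressor
    speed_model: RandomForestRegressor

    def predict(self, radius, types, depth) -> tuple[np.ndarray, np.ndarray]:
        X = _features(radius, types, depth)
        po2 = np.clip(self.po2_model.predict(X), 0.0, None)
        speed = np.clip(self.speed_model.predict(X), 0.0, None)
        return po2, speed

    def save(self, path) -> None:
        """Persist both fitted forests to a single joblib file."""
        import joblib

        joblib.dump({"po2": self.po2_model, "speed": self.speed_model}, path)

    @classmethod
    def load(cls, path) -> "PhysioForest":
        import joblib

        d = joblib.load(path)
        return cls(po2_model=d["po2"], speed_model=d["speed"])


def fit_physio_forest(
    records: pd.DataFrame,
    n_trees: int = 100,
    max_depth: int = 10,
    min_split: int = 2,
    bootstrap: bool = True,
    seed: int = 0,
) -> PhysioForest:
    """Fit the two random-forest regressors on a physiology table.

    Forest architecture: 100 trees, maximum depth 10, minimum samples to
    split 2, bootstrap resampling, MSE split criterion.
    """
    if len(records) < 2:
        raise ValidationError("need at least 2 records to fit")
    X = _features(records["radius_um"], records["type"], records["depth_um"])
    kw = dict(
        n_estimators=n_trees,
        max_depth=max_depth,
        min_samples_split=min_split,
        bootstrap=bootstrap,
        criterion="squared_error",
    )
    po2_model = RandomForestRegressor(random_state=seed, **kw).fit(X, records["po2_mmHg"])
    speed_model = RandomForestRegressor(random_state=seed + 1, **kw).fit(X, records["speed_mm_s"])
    return PhysioForest(po2_model, speed_model)


def predict_physiology(models: PhysioForest, network: VascularNetwork) -> VascularNetwork:
    """Populate per-edge ``speed`` (mm/s) and ``po2`` (mmHg) in place."""
    if any(e.vessel_type is None for e in network.edges):
        raise ValidationError("vessel types must be assigned before physiology prediction")
    geo = segment_geometry(network)
    types = [e.vessel_type for e in network.edges]
    po2, speed = models.predict(geo["radius"], types, geo["depth"])
    for e, p, v in zip(network.edges, po2, speed):
        e.po2 = float(p)
        e.speed = float(v)
    return network


# ---------------------------------------------------------------------------
# Hill conversion and hematocrit
# ---------------------------------------------------------------------------


def hill_so2(po2, constants: PhysioConstants = PhysioConstants()):
    """Hemoglobin saturation from PO2 via the Hill equation.

    SO2 = PO2^h / (PO2^h + P50^h); SO2(P50) = 1/2 exactly.
    """
    po2 = np.asarray(po2, dtype=float)
    if np.any(po2 < 0):
        raise ValidationError("po2 must be >= 0")
    ph = po2 ** constants.hill_h
    out = ph / (ph + constants.hill_p50 ** constants.hill_h)
    return out if out.ndim else float(out)


def assign_hematocrit(network: VascularNetwork, constants: PhysioConstants = PhysioConstants()) -> VascularNetwork:
    """Hematocrit by vessel class: capillary 0.33, artery/vein 0.44."""
    for e in network.edges:
        if e.vessel_type is None:
            raise ValidationError("vessel types must be assigned before hematocrit")
        e.hematocrit = constants.hct_capillary if e.vessel_type is VesselType.CAPILLARY else constants.hct_large
    return network


def assign_so2(network: VascularNetwork, constants: PhysioConstants = PhysioConstants()) -> VascularNetwork:
    """Populate per-edge SO2 from PO2 via the Hill equation."""
    for e in network.edges:
        if e.po2 is None:
            raise ValidationError("po2 must be predicted before SO2 conversion")
        e.so2 = float(hill_so2(e.po2, constants))
    return network
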