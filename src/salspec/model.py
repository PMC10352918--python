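"""PLSR calibration of layer-averaged root-zone salinity.

The response is one of three cumulative layer averages of soil EC_1:5:
S1 = EC(0-20 cm), S2 = mean of 0-20 and 20-40, S3 = mean of all three layers
down to 60 cm. Predictors are preprocessed canopy reflectance bands (R or
FDR), optionally restricted to a selected subset and optionally augmented
with growth covariates (plant height H, aboveground biomass AGB, shoot water
content SWC).

Conventions (leakage-free throughout):

* the calibration/validation split is stratified by growth stage — 20 of the
  28 records per stage go to calibration (100/40 overall on the default
  layout) — and is reproducible given a seed;
* spectral columns are mean-centred only (shared units), covariates are
  autoscaled, both with calibration statistics;
* wavelength selection runs inside the calibration partition only (a
  ``selection_scope="all"`` mode is available for comparison);
* the latent-variable count minimises RMSECV with ties to the smaller count.

Negative salinity predictions are reported as-is (flagged in the grid
metadata), never clipped.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace as dc_replace

import numpy as np
import pandas as pd

from . import preprocess as prep
from .metrics import evaluate
from .pls import best_lv, fit_plsr
from .selection import (
    CARSParams,
    RFAParams,
    SelectionResult,
    VIPParams,
    cars_select,
    random_frog_select,
    vip_scores,
)

__all__ = [
    "SampleRecord",
    "layer_targets",
    "compute_targets",
    "split_dataset",
    "augment_with_covariates",
    "GridConfig",
    "run_experiment_grid",
    "RESULT_COLUMNS",
]

COVARIATE_COLUMNS = {"H": "H_cm", "AGB": "AGB_g", "SWC": "SWC_frac"}
LAYER_LABELS = ("S1", "S2", "S3")
DEFAULT_STAGES = (76, 111, 124, 142, 162)

RESULT_COLUMNS = [
    "layer", "preprocessing", "selector", "covariates", "n_features",
    "LV", "R2_C", "RMSE_C", "R2_V", "RMSE_V", "LCCC",
]


@dataclass
class SampleRecord:
    """One field observation: spectrum + growth parameters + layered EC."""

    sample_id: str
    treatment: str
    stage_das: int
    spectrum: prep.Spectrum
    H: float  # plant height, cm
    AGB: float  # aboveground biomass, g per plant
    SWC: float  # shoot water content, fraction
    ec_layers: tuple[float, float, float]  # EC_1:5 dS/m for 0-20/20-40/40-60 cm

    def __post_init__(self):
        if self.H <= 0:
            raise ValueError("plant height must be positive")
        if self.AGB < 0:
            raise ValueError("aboveground biomass must be non-negative")
        if not 0 < self.SWC < 1:
            raise ValueError("shoot water content must be a fraction in (0, 1)")
        if any(e is not None and e <= 0 for e in self.ec_layers):
            raise ValueError("EC values must be positive")


def layer_targets(ec_layers, layers=LAYER_LABELS) -> dict[str, float]:
    """Cumulative layer averages from per-layer EC values.

    ``ec_layers`` holds EC_1:5 for (0-20, 20-40, 40-60 cm); trailing entries
    may be None/NaN if the corresponding targets are not requested.
    """
    ecs = list(ec_layers) + [None] * (3 - len(ec_layers))
    need = {"S1": 1, "S2": 2, "S3": 3}
    out = {}
    for label in layers:
        k = need[label]
        vals = ecs[:k]
        if any(v is None or not np.isfinite(v) for v in vals):
            raise ValueError(f"{label} requires the first {k} layer EC values")
        out[label] = float(np.mean([float(v) for v in vals]))
    return out


def compute_targets(samples: pd.DataFrame) -> pd.DataFrame:
    """Add S1/S2/S3 columns from ec_0_20/ec_20_40/ec_40_60."""
    out = samples.copy()
    out["S1"] = out["ec_0_20"]
    out["S2"] = (out["ec_0_20"] + out["ec_20_40"]) / 2.0
    out["S3"] = (out["ec_0_20"] + out["ec_20_40"] + out["ec_40_60"]) / 3.0
    return out


def split_dataset(
    samples: pd.DataFrame,
    per_stage_calibration_n: int = 20,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Stage-stratified calibration/validation split.

    Returns positional index arrays (calibration, validation); disjoint and
    exhaustive, reproducible given the seed.
    """
    rng = np.random.default_rng(seed)
    cal, val = [], []
    pos = np.arange(len(samples))
    stages = samples["stage_das"].to_numpy()
    for das in np.unique(stages):
        idx = pos[stages == das]
        if idx.size < per_stage_calibration_n:
            raise ValueError(
                f"stage {das} DAS has {idx.size} < {per_stage_calibration_n} records"
            )
        chosen = rng.choice(idx, size=per_stage_calibration_n, replace=False)
        cal.append(np.sort(chosen))
        val.append(np.setdiff1d(idx, chosen))
    return np.concatenate(cal), np.concatenate(val)


def augment_with_covariates(
    X_spec: np.ndarray,
    samples: pd.DataFrame,
    covariates: tuple[str, ...] = (),
    stats: dict | None = None,
):
    """Append autoscaled covariate columns to a spectral design matrix.

    ``stats`` carries the training means/sds; pass the dict returned from the
    calibration call when transforming validation rows so that no validation
    statistic leaks into the scaling.

    Returns ``(X, stats)``.
    """
    X_spec = np.asarray(X_spec, dtype=float)
    if not covariates:
        return X_spec, {"names": (), "mean": np.empty(0), "sd": np.empty(0)}
    cols = []
    for name in covariates:
        col = COVARIATE_COLUMNS.get(name, name)
        if col not in samples.columns:
            raise KeyError(f"covariate {name!r} (column {col!r}) missing")
        vals = samples[col].to_numpy(dtype=float)
        if np.any(~np.isfinite(vals)):
            raise ValueError(f"covariate {name!r} has missing values")
        cols.append(vals)
    C = np.column_stack(cols)
    if stats is None:
        mean = C.mean(axis=0)
        sd = C.std(axis=0, ddof=0)
        if np.any(sd == 0):
            raise ValueError("constant covariate cannot be autoscaled")
        stats = {"names": tuple(covariates), "mean": mean, "sd": sd}
    else:
        if tuple(stats["names"]) != tuple(covariates):
            raise ValueError("stats were computed for different covariates")
    C = (C - stats["mean"]) / stats["sd"]
    return np.hstack([X_spec, C]), stats


@dataclass
class GridConfig:
    """Configuration of the preprocessing x selector x covariates x layer grid."""

    preprocessings: tuple[str, ...] = ("R", "FDR")
    selectors: tuple[str, ...] = ("full", "VIP", "CARS", "RFA")
    covariate_sets: tuple[tuple[str, ...], ...] = ((), ("H",), ("H", "SWC"), ("H", "AGB", "SWC"))
    layers: tuple[str, ...] = ("S1", "S2", "S3")
    trim_windows: tuple = prep.DEFAULT_TRIM_WINDOWS
    sg_window: int = 13
    sg_polyorder: int = 2
    per_stage_calibration_n: int = 20
    max_lv: int = 10
    cv_folds: int = 5
    selection_scope: str = "calibration"  # or "all"
    vip: VIPParams = field(default_factory=VIPParams)
    cars: CARSParams = field(default_factory=CARSParams)
    # run-scale random-frog settings (protocol-scale defaults live on RFAParams)
    rfa: RFAParams = field(default_factory=lambda: RFAParams(n_chain_iters=250, burn_in=50, n_restarts=10))


def preprocess_matrix(wavelengths, reflectance, config: GridConfig):
    """Trim + smooth (R) and derivative (FDR) matrices for a sample block."""
    wl, raw = prep.trim_bands(wavelengths, reflectance, config.trim_windows)
    R = prep.sg_smooth(wl, raw, config.sg_window, config.sg_polyorder)
    FDR = prep.first_derivative(wl, R, config.sg_window, config.sg_polyorder)
    return wl, {"R": R, "FDR": FDR}


def _stage_seed(master: int, label: str) -> int:
    """Deterministic per-stage seed fan-out from the master seed."""
    import zlib

    ss = np.random.SeedSequence([int(master), zlib.crc32(label.encode())])
    return int(ss.generate_state(1)[0] % (2**31 - 1))


def _run_selector(name, X, y, wl, config: GridConfig, seed: int) -> SelectionResult | None:
    if name == "full":
        return None
    if name == "VIP":
        return vip_scores(X, y, dc_replace(config.vip, max_lv=config.max_lv,
                                           cv_folds=config.cv_folds), wl, seed=seed)
    if name == "CARS":
        return cars_select(X, y, dc_replace(config.cars, max_lv=config.max_lv,
                                            cv_folds=config.cv_folds), wl, seed=seed)
    if name == "RFA":
        return random_frog_select(X, y, dc_replace(config.rfa, max_lv=config.max_lv,
                                                   cv_folds=config.cv_folds), wl, seed=seed)
    raise ValueError(f"unknown selector {name!r}")


def fit_cell(
    X_cal, X_val, samples_cal, samples_val, y_cal, y_val,
    covariates, max_lv, cv_folds, seed, fixed_lv=None,
):
    """Fit one grid cell and return its Table-style metric row pieces.

    ``fixed_lv`` pins the latent-variable count (used to keep a selector
    cell consistent with the LV its selection bookkeeping optimised);
    otherwise the count comes from an RMSECV scan.
    """
    Xc, stats = augment_with_covariates(X_cal, samples_cal, covariates)
    Xv, _ = augment_with_covariates(X_val, samples_val, covariates, stats=stats)
    n_spec = X_cal.shape[1]
    # spectra centred only; covariates already autoscaled
    if fixed_lv is None:
        cap = min(max_lv, Xc.shape[0] - int(np.ceil(Xc.shape[0] / cv_folds)) - 1, Xc.shape[1])
        lv, _, _ = best_lv(Xc, y_cal, max_lv=cap, folds=cv_folds, seed=seed)
    else:
        lv = min(fixed_lv, Xc.shape[0] - 1, Xc.shape[1])
    model = fit_plsr(Xc, y_cal, lv)
    pred_c = model.predict(Xc)
    pred_v = model.predict(Xv)
    rep_c = evaluate(y_cal, pred_c, "calibration")
    rep_v = evaluate(y_val, pred_v, "validation")
    return {
        "n_features": Xc.shape[1],
        "n_spectral": n_spec,
        "LV": model.n_lv,
        "R2_C": rep_c["r2"],
        "RMSE_C": rep_c["rmse"],
        "R2_V": rep_v["r2"],
        "RMSE_V": rep_v["rmse"],
        "LCCC": rep_v["lccc"],
        "negative_predictions": int((pred_v < 0).sum() + (pred_c < 0).sum()),
        "model": model,
    }


def run_experiment_grid(
    samples: pd.DataFrame,
    wavelengths: np.ndarray,
    reflectance: np.ndarray,
    config: GridConfig | None = None,
    seed: int = 0,
    return_selections: bool = False,
):
    """Run the full evaluation grid and return one metric row per cell.

    ``samples`` must carry stage_das, the growth columns, and the per-layer
    EC columns; ``reflectance`` is the raw (n, p) matrix aligned with
    ``wavelengths``. Selection is run once per (preprocessing, layer,
    selector) and shared across covariate sets.
    """
    config = config or GridConfig()
    for name in config.selectors:
        if name not in ("full", "VIP", "CARS", "RFA"):
            raise ValueError(f"unknown selector {name!r}")
    for label in config.layers:
        if label not in LAYER_LABELS:
            raise ValueError(f"unknown layer {label!r}")
    samples = compute_targets(samples.reset_index(drop=True))
    wl, mats = preprocess_matrix(wavelengths, reflectance, config)
    cal, val = split_dataset(samples, config.per_stage_calibration_n,
                             seed=_stage_seed(seed, "split"))
    s_cal, s_val = samples.iloc[cal], samples.iloc[val]

    rows = []
    selections: dict[tuple, SelectionResult | None] = {}
    for pname in config.preprocessings:
        if pname not in mats:
            raise ValueError(f"unknown preprocessing {pname!r}")
        M = mats[pname]
        for layer in config.layers:
            y = samples[layer].to_numpy(dtype=float)
            y_cal, y_val = y[cal], y[val]
            for sel_name in config.selectors:
                sel_seed = _stage_seed(seed, f"select/{pname}/{layer}/{sel_name}")
                if config.selection_scope == "calibration":
                    sel = _run_selector(sel_name, M[cal], y_cal, wl, config, sel_seed)
                elif config.selection_scope == "all":
                    sel = _run_selector(sel_name, M, y, wl, config, sel_seed)
                else:
                    raise ValueError(f"unknown selection_scope {config.selection_scope!r}")
                selections[(pname, layer, sel_name)] = sel
                cols = slice(None) if sel is None else sel.support
                for covs in config.covariate_sets:
                    # a selector cell keeps the LV its RMSECV bookkeeping
                    # chose; covariate-augmented cells re-scan on the same
                    # fold stream the selector optimised against
                    if sel is None:
                        cell_seed = _stage_seed(seed, f"fit/{pname}/{layer}/{sel_name}")
                        fixed = None
                    else:
                        cell_seed = sel_seed
                        fixed = sel.n_lv if not covs else None
                    res = fit_cell(
                        M[cal][:, cols], M[val][:, cols], s_cal, s_val,
                        y_cal, y_val, covs, config.max_lv, config.cv_folds, cell_seed,
                        fixed_lv=fixed,
                    )
                    rows.append(
                        {
                            "layer": layer,
                            "preprocessing": pname,
                            "selector": sel_name,
                            "covariates": "+".join(covs) if covs else "none",
                            **{k: v for k, v in res.items() if k != "model"},
                        }
                    )
    table = pd.DataFrame(rows)
    table = table[RESULT_COLUMNS + ["n_spectral", "negative_predictions"]]
    if return_selections:
        return table, selections
    return table
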