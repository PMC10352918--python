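"""Shared fixtures: synthetic datasets and the multi-seed ordering study."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import salspec
from salspec.metrics import r_squared
from salspec.model import (
    GridConfig,
    compute_targets,
    run_experiment_grid,
    split_dataset,
    _stage_seed,
)


@pytest.fixture(scope="session")
def default_dataset():
    """One default-configuration draw (seed 42), reused across read-only tests."""
    return salspec.generate_dataset(seed=42)


@pytest.fixture(scope="session")
def default_samples(default_dataset):
    return compute_targets(default_dataset.samples)


def _oracle_ceiling(samples: pd.DataFrame, seed: int) -> float:
    """Validation R^2 of a linear fit on the generator latents + covariates.

    The canopy-effective salinity is the most any spectral inversion could
    recover from the spectra; together with the measured growth covariates it
    bounds the pipeline's achievable accuracy.
    """
    cal, val = split_dataset(samples, 20, seed=_stage_seed(seed, "split"))
    y = samples["S2"].to_numpy(dtype=float)
    X = samples[["ec_canopy", "H_cm", "SWC_frac"]].to_numpy(dtype=float)
    A = np.hstack([X[cal], np.ones((cal.size, 1))])
    beta = np.linalg.lstsq(A, y[cal], rcond=None)[0]
    pred = np.hstack([X[val], np.ones((val.size, 1))]) @ beta
    return r_squared(y[val], pred)


@pytest.fixture(scope="session")
def ordering_study():
    """Ten-seed study of the FDR model chain used by several invariants.

    For each seed: validation R^2 of the FDR full-spectrum model, the
    FDR+CARS spectra-only model, the FDR+CARS+{H,SWC} model, and the
    generative oracle ceiling.
    """
    cfg = GridConfig(
        preprocessings=("FDR",),
        selectors=("full", "CARS"),
        covariate_sets=((), ("H", "SWC")),
        layers=("S2",),
    )
    records = []
    for seed in range(1, 11):
        ds = salspec.generate_dataset(seed=seed)
        samples = compute_targets(ds.samples)
        tab = run_experiment_grid(ds.samples, ds.wavelengths, ds.reflectance, cfg, seed=seed)
        pick = lambda sel, cov: float(
            tab[(tab.selector == sel) & (tab.covariates == cov)]["R2_V"].iloc[0]
        )
        records.append(
            {
                "seed": seed,
                "full": pick("full", "none"),
                "cars": pick("CARS", "none"),
                "cars_cov": pick("CARS", "H+SWC"),
                "ceiling": _oracle_ceiling(samples, seed),
            }
        )
    return pd.DataFrame(records)
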