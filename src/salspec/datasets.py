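"""Bundled reference tables.

The package ships the layer-averaged root-zone soil salinity observations
(EC_1:5, dS m^-1) from a multi-year saline-soil amelioration trial in a
drip-irrigated cotton field: four treatments (T1..T4, ordered T2 < T1 < T3 < T4
by overall salinity), five sampling stages (76-162 days after sowing), and the
three cumulative layer averages S1 (0-20 cm), S2 (0-40 cm), S3 (0-60 cm).
Values are means +/- sd over 7 field replicates.

These numbers serve two purposes: they are the worked-example input for the
percent-change arithmetic in :mod:`salspec.metrics`, and they seed the default
salinity surface of the synthetic generator in :mod:`salspec.simulate`.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

TREATMENTS = ("T1", "T2", "T3", "T4")
STAGES_DAS = (76, 111, 124, 142, 162)
LAYERS = ("S1", "S2", "S3")

# mean EC_1:5 (dS/m), shape (layer, stage, treatment) with sd companion.
_EC_MEAN = {
    "S1": [
        [2.44, 2.39, 2.82, 4.56],
        [2.35, 2.34, 2.74, 4.28],
        [2.24, 2.30, 2.57, 3.83],
        [2.33, 2.35, 2.86, 3.87],
        [2.42, 2.41, 3.13, 3.99],
    ],
    "S2": [
        [2.65, 2.35, 2.80, 4.32],
        [2.54, 2.27, 2.69, 3.96],
        [2.33, 2.23, 2.66, 3.72],
        [2.47, 2.29, 2.85, 3.80],
        [2.55, 2.33, 2.98, 3.86],
    ],
    "S3": [
        [2.81, 2.24, 3.15, 4.37],
        [2.70, 2.13, 2.88, 4.15],
        [2.65, 2.03, 2.85, 3.85],
        [2.79, 2.21, 3.24, 4.25],
        [2.84, 2.28, 3.35, 4.37],
    ],
}

_EC_SD = {
    "S1": [
        [0.44, 0.39, 0.28, 0.93],
        [0.13, 0.26, 0.44, 0.54],
        [0.54, 0.26, 0.48, 0.23],
        [0.45, 0.51, 0.27, 0.30],
        [0.55, 0.29, 0.65, 0.66],
    ],
    "S2": [
        [0.52, 0.37, 0.46, 0.88],
        [0.19, 0.25, 0.51, 0.71],
        [0.67, 0.28, 0.60, 0.42],
        [0.26, 0.48, 0.25, 0.25],
        [0.53, 0.34, 0.69, 0.73],
    ],
    "S3": [
        [0.62, 0.34, 0.52, 0.80],
        [0.25, 0.42, 0.37, 0.57],
        [0.41, 0.38, 0.63, 0.43],
        [0.32, 0.35, 0.24, 0.32],
        [0.52, 0.51, 0.82, 0.93],
    ],
}


def load_field_ec() -> pd.DataFrame:
    """Tidy table of layer-averaged soil EC_1:5 by treatment and stage.

    Returns
    -------
    DataFrame with columns ``layer`` (S1/S2/S3), ``das`` (days after sowing),
    ``treatment`` (T1..T4), ``ec`` (mean EC_1:5, dS/m) and ``sd``.
    """
    rows = []
    for layer in LAYERS:
        for i, das in enumerate(STAGES_DAS):
            for j, trt in enumerate(TREATMENTS):
                rows.append(
                    {
                        "layer": layer,
                        "das": das,
                        "treatment": trt,
                        "ec": _EC_MEAN[layer][i][j],
                        "sd": _EC_SD[layer][i][j],
                    }
                )
    return pd.DataFrame(rows)


def layer_mean_array() -> np.ndarray:
    """Cumulative layer-average EC means as an array.

    Shape ``(n_treatments, n_stages, 3)`` with the last axis ordered
    (S1, S2, S3).
    """
    arr = np.empty((len(TREATMENTS), len(STAGES_DAS), 3))
    for k, layer in enumerate(LAYERS):
        arr[:, :, k] = np.asarray(_EC_MEAN[layer]).T
    return arr


def layer_sd_array() -> np.ndarray:
    """Companion sd array, same shape as :func:`layer_mean_array`."""
    arr = np.empty((len(TREATMENTS), len(STAGES_DAS), 3))
    for k, layer in enumerate(LAYERS):
        arr[:, :, k] = np.asarray(_EC_SD[layer]).T
    return arr


def per_layer_means() -> np.ndarray:
    """Invert cumulative averages into per-layer EC means.

    S1 = EC(0-20), S2 = mean(EC(0-20), EC(20-40)), S3 = mean of all three,
    hence EC(20-40) = 2*S2 - S1 and EC(40-60) = 3*S3 - 2*S2.

    Shape ``(n_treatments, n_stages, 3)``, last axis = (0-20, 20-40, 40-60 cm).
    """
    cum = layer_mean_array()
    s1, s2, s3 = cum[..., 0], cum[..., 1], cum[..., 2]
    out = np.stack([s1, 2.0 * s2 - s1, 3.0 * s3 - 2.0 * s2], axis=-1)
    return out
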