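"""Model evaluation and field-arithmetic helpers.

The calibration/validation metrics are the coefficient of determination
R^2 = 1 - SSE/SST, the root mean square error RMSE = sqrt(mean((y - yhat)^2))
(dS/m for salinity), and Lin's concordance correlation coefficient

    LCCC = 2 rho sigma_y sigma_yhat / (sigma_y^2 + sigma_yhat^2 + (mu_y - mu_yhat)^2)

which penalises both imprecision (departure from the regression line) and
bias (departure of that line from the 1:1 line); |LCCC| <= |rho| always.
Variances use the population (1/n) convention by default.

Also here: the percent-change arithmetic used to summarise stage-to-stage
salinity decreases and preprocessing gains in band-target correlations, and
the growth-parameter vs layer-salinity correlation matrix.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

__all__ = [
    "r_squared",
    "rmse",
    "pearson_r",
    "lccc",
    "evaluate",
    "percent_change",
    "round_half_up",
    "percent_decrease_range",
    "growth_salinity_correlation",
    "EvalReport",
]


def _pair(y, yhat):
    y = np.asarray(y, dtype=float).ravel()
    yhat = np.asarray(yhat, dtype=float).ravel()
    if y.shape != yhat.shape:
        raise ValueError(f"length mismatch: {y.shape[0]} vs {yhat.shape[0]}")
    return y, yhat


def r_squared(y, yhat) -> float:
    """1 - SSE/SST; undefined (raises) for constant measured values."""
    y, yhat = _pair(y, yhat)
    if y.size < 2:
        raise ValueError("need at least 2 samples")
    sst = float(((y - y.mean()) ** 2).sum())
    if sst == 0:
        raise ValueError("R^2 undefined for constant measured values")
    sse = float(((y - yhat) ** 2).sum())
    return 1.0 - sse / sst


def rmse(y, yhat) -> float:
    y, yhat = _pair(y, yhat)
    if y.size < 1:
        raise ValueError("need at least 1 sample")
    return float(np.sqrt(np.mean((y - yhat) ** 2)))


def pearson_r(y, yhat) -> float:
    y, yhat = _pair(y, yhat)
    yc, pc = y - y.mean(), yhat - yhat.mean()
    denom = float(np.sqrt((yc**2).sum() * (pc**2).sum()))
    if denom == 0:
        raise ValueError("Pearson r undefined for constant input")
    return float((yc @ pc) / denom)


def lccc(y, yhat, variance: str = "population") -> float:
    """Lin's concordance correlation coefficient.

    ``variance`` selects the 1/n ("population", standard Lin definition) or
    1/(n-1) ("sample") convention; the choice cancels from rho but not from
    the bias term's relative weight.
    """
    y, yhat = _pair(y, yhat)
    if y.size < 2:
        raise ValueError("need at least 2 samples")
    ddof = 0 if variance == "population" else 1
    sy2 = float(np.var(y, ddof=ddof))
    sp2 = float(np.var(yhat, ddof=ddof))
    if sy2 == 0 or sp2 == 0:
        raise ValueError("LCCC undefined for constant input")
    cov = float(np.mean((y - y.mean()) * (yhat - yhat.mean())))
    if ddof == 1:
        cov *= y.size / (y.size - 1)
    return 2.0 * cov / (sy2 + sp2 + (y.mean() - yhat.mean()) ** 2)


class EvalReport(dict):
    """Metric bundle for one partition: r2, rmse, lccc, n, partition."""


def evaluate(y, yhat, partition: str = "validation") -> EvalReport:
    return EvalReport(
        r2=r_squared(y, yhat),
        rmse=rmse(y, yhat),
        lccc=lccc(y, yhat),
        n=int(np.asarray(y).size),
        partition=partition,
    )


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal half-up rounding (2.675 -> 2.68), used for reported percents."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def percent_change(baseline: float, new: float, mode: str = "signed") -> float:
    """100*(new - baseline)/baseline.

    ``mode="decrease"`` reports a drop as a positive magnitude (and a rise as
    negative), matching how stage-to-stage salinity decreases are quoted.
    """
    if baseline == 0:
        raise ValueError("percent change undefined for zero baseline")
    pct = 100.0 * (new - baseline) / baseline
    if mode == "decrease":
        return -pct
    if mode != "signed":
        raise ValueError(f"unknown mode {mode!r}")
    return pct


def percent_decrease_range(
    ec_table: pd.DataFrame,
    layer: str,
    das_from: int,
    das_to: int,
    ndigits: int = 2,
) -> tuple[float, float]:
    """(min %, max %) salinity decrease across treatments between two stages.

    ``ec_table`` is tidy with columns layer/das/treatment/ec (see
    :func:`salspec.datasets.load_field_ec`). Both stages must be present for
    every treatment.
    """
    sub = ec_table[ec_table["layer"] == layer]
    a = sub[sub["das"] == das_from].set_index("treatment")["ec"]
    b = sub[sub["das"] == das_to].set_index("treatment")["ec"]
    treatments = sorted(set(a.index) | set(b.index))
    if not treatments or a.reindex(treatments).isna().any() or b.reindex(treatments).isna().any():
        raise ValueError(f"missing table cells for layer {layer} at {das_from}/{das_to} DAS")
    drops = [
        percent_change(float(a[t]), float(b[t]), mode="decrease") for t in treatments
    ]
    return (
        round_half_up(min(drops), ndigits),
        round_half_up(max(drops), ndigits),
    )


GROWTH_COLUMNS = {"H": "H_cm", "AGB": "AGB_g", "SWC": "SWC_frac"}
TARGET_COLUMNS = ("S1", "S2", "S3")


def growth_salinity_correlation(
    samples: pd.DataFrame, by_stage: bool = False
) -> pd.DataFrame:
    """Pearson r between growth parameters {H, AGB, SWC} and {S1, S2, S3}.

    Pooled over all records by default, or per growth stage with
    ``by_stage=True`` (rows indexed by (stage_das, parameter)). Cells with
    fewer than 3 records or zero variance are NaN.
    """

    def _block(df: pd.DataFrame) -> pd.DataFrame:
        out = pd.DataFrame(index=list(GROWTH_COLUMNS), columns=list(TARGET_COLUMNS), dtype=float)
        for gname, gcol in GROWTH_COLUMNS.items():
            for tname in TARGET_COLUMNS:
                x = df[gcol].to_numpy(dtype=float)
                y = df[tname].to_numpy(dtype=float)
                if x.size < 3 or np.std(x) == 0 or np.std(y) == 0:
                    out.loc[gname, tname] = np.nan
                else:
                    out.loc[gname, tname] = pearson_r(x, y)
        return out

    if not by_stage:
        return _block(samples)
    blocks = []
    for das, df in samples.groupby("stage_das"):
        blk = _block(df)
        blk.index = pd.MultiIndex.from_product([[das], blk.index], names=["stage_das", "parameter"])
        blocks.append(blk)
    return pd.concat(blocks)
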