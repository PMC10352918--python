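"""CSV I/O for sample tables and spectra.

Spectra travel as *wide* CSV — first column ``sample_id``, remaining columns
named by integer wavelength (nm), header required to be strictly increasing —
or as *long* CSV with columns (sample_id, wavelength_nm, reflectance). The
sample table carries sample_id, treatment, stage_das, growth parameters
(H_cm, AGB_g, SWC_frac) and per-layer EC (ec_0_20, ec_20_40, ec_40_60).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "Dataset",
    "read_spectra_wide",
    "read_spectra_long",
    "write_spectra_wide",
    "read_samples",
    "write_selection",
]

SAMPLE_COLUMNS = [
    "sample_id", "treatment", "stage_das", "H_cm", "AGB_g", "SWC_frac",
    "ec_0_20", "ec_20_40", "ec_40_60",
]


@dataclass
class Dataset:
    """Sample table plus aligned reflectance matrix on a shared grid."""

    samples: pd.DataFrame
    wavelengths: np.ndarray
    reflectance: np.ndarray  # (n_samples, n_bands)

    def __post_init__(self):
        if self.reflectance.shape != (len(self.samples), self.wavelengths.size):
            raise ValueError("reflectance shape must be (n_samples, n_bands)")

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.samples.to_csv(outdir / "samples.csv", index=False)
        write_spectra_wide(
            outdir / "spectra.csv",
            self.samples["sample_id"].tolist(),
            self.wavelengths,
            self.reflectance,
        )

    @classmethod
    def read(cls, indir: str | Path) -> "Dataset":
        indir = Path(indir)
        samples = read_samples(indir / "samples.csv")
        ids, wl, refl = read_spectra_wide(indir / "spectra.csv")
        order = {sid: i for i, sid in enumerate(ids)}
        idx = [order[sid] for sid in samples["sample_id"]]
        return cls(samples=samples, wavelengths=wl, reflectance=refl[idx])


def write_spectra_wide(path, sample_ids, wavelengths, reflectance) -> None:
    df = pd.DataFrame(
        np.asarray(reflectance),
        columns=[str(int(w)) if float(w).is_integer() else str(w) for w in wavelengths],
    )
    df.insert(0, "sample_id", list(sample_ids))
    df.to_csv(path, index=False)


def read_spectra_wide(path):
    """Returns (sample_ids, wavelengths, reflectance matrix)."""
    df = pd.read_csv(path)
    if df.columns[0] != "sample_id":
        raise ValueError("wide spectra CSV must start with a sample_id column")
    wl = np.array([float(c) for c in df.columns[1:]])
    if wl.size == 0 or np.any(np.diff(wl) <= 0):
        raise ValueError("wavelength header must be strictly increasing")
    return df["sample_id"].tolist(), wl, df.iloc[:, 1:].to_numpy(dtype=float)


def read_spectra_long(path):
    """Long format (sample_id, wavelength_nm, reflectance) -> wide triplet."""
    df = pd.read_csv(path)
    need = {"sample_id", "wavelength_nm", "reflectance"}
    if not need.issubset(df.columns):
        raise ValueError(f"long spectra CSV needs columns {sorted(need)}")
    wide = df.pivot(index="sample_id", columns="wavelength_nm", values="reflectance")
    wide = wide.sort_index(axis=1)
    if wide.isna().any().any():
        raise ValueError("long spectra are not on a common wavelength grid")
    return wide.index.tolist(), wide.columns.to_numpy(dtype=float), wide.to_numpy(dtype=float)


def read_samples(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in SAMPLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"sample table missing columns: {missing}")
    return df


def write_selection(sel, outdir: str | Path, stem: str | None = None) -> None:
    """Selection result -> (wavelength, score, selected) CSV + JSON sidecar."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stem = stem or sel.method.lower()
    pd.DataFrame(
        {
            "wavelength_nm": sel.wavelengths,
            "score": sel.scores,
            "selected": sel.support.astype(int),
        }
    ).to_csv(outdir / f"{stem}_scores.csv", index=False)
    meta = {
        "method": sel.method,
        "seed": int(sel.seed),
        "best_rmsecv": float(sel.best_rmsecv),
        "n_lv": int(sel.n_lv),
        "n_selected": int(sel.n_selected),
        "rmsecv_trace": [float(v) for v in sel.rmsecv_trace],
        "params": {k: v for k, v in sel.params.items()},
    }
    with open(outdir / f"{stem}_meta.json", "w") as fh:
        json.dump(meta, fh, indent=2, default=str)
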