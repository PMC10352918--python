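"""Synthetic cotton-field generator.

Every stage of the pipeline is testable without field data: this module
draws datasets with the statistical structure the analysis assumes —

* **Layered salinity.** Per-layer EC_1:5 means by treatment and stage default
  to the bundled field-trial table (:mod:`salspec.datasets`): four
  treatments ordered T2 < T1 < T3 < T4 in overall root-zone salinity, five
  stages whose trajectory dips to its minimum at 124 days after sowing
  (irrigation leaching) and rises again once irrigation stops.
* **Growth parameters.** Plant height follows a logistic curve in DAS that
  plateaus after 142 DAS; aboveground biomass rises logistically and peaks
  earlier under high salinity; shoot water content declines linearly. Each is
  suppressed by root-zone salinity (S2) with a per-stage slope that
  attenuates over the season, so the salinity-growth correlations are
  negative everywhere and weaken with stage.
* **Canopy spectra.** A parametric vegetation curve (green peak near 550 nm,
  red edge at 680-750 nm, NIR plateau, water troughs near 1450/1940 nm) on
  the full 350-2500 nm @ 1 nm grid. Salinity shifts it through a *canopy-
  effective* salinity (the record's S2 plus zero-mean perception noise,
  reflecting root-zone heterogeneity the canopy integrates over): visible
  reflectance increases and long-wave infrared reflectance decreases with
  salinity, and a configurable set of narrow informative bands carries an
  additional linear signal. Biomass nudges the NIR plateau and shoot water
  deepens the water troughs. Noise is AR(1)-correlated along wavelength to
  imitate instrument smoothness. Values are clipped to [0, 1.2].

The canopy-effective salinity is stored per record (``ec_canopy``) so tests
can compute the generative accuracy ceiling; it is a latent diagnostic, not
a pipeline input. All draws are deterministic under the master seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from . import datasets
from .io import Dataset

__all__ = ["SyntheticConfig", "generate_salinity", "generate_growth",
           "generate_spectra", "generate_dataset", "write_dataset"]


def _gauss(x, mu, sigma):
    return np.exp(-0.5 * ((x - mu) / sigma) ** 2)


def _sig(x):
    return 1.0 / (1.0 + np.exp(-x))


@dataclass
class SyntheticConfig:
    treatments: tuple[str, ...] = datasets.TREATMENTS
    stages_das: tuple[int, ...] = datasets.STAGES_DAS
    n_reps: int = 7

    # --- salinity (dS/m) ---
    # per-layer EC means, shape (treatment, stage, layer 0-20/20-40/40-60)
    ec_layer_means: np.ndarray = field(default_factory=datasets.per_layer_means)
    ec_sd: float = 0.35  # within-treatment replicate scatter per layer
    ec_floor: float = 0.05

    # --- growth responses (all salinity slopes positive = suppression) ---
    h_max: float = 90.0          # cm, logistic asymptote
    h_mid_das: float = 90.0
    h_tau: float = 18.0
    h_plateau_das: float = 142.0
    h_sal_slope: float = 6.0     # cm per dS/m at the first stage
    h_noise_sd: float = 3.0
    agb_max: float = 130.0       # g/plant
    agb_mid_das: float = 108.0
    agb_tau: float = 10.0
    agb_peak_das: tuple[float, ...] = (142.0, 142.0, 124.0, 124.0)  # per treatment
    agb_decline: float = 0.12    # fractional drop over 38 DAS past the peak
    agb_sal_rel: float = 0.12    # fractional suppression per dS/m at the first stage
    agb_noise_cv: float = 0.10   # noise sd as a fraction of the stage baseline
    swc_start: float = 0.82      # fraction at 76 DAS
    swc_decline_per_das: float = 0.0012
    swc_sal_slope: float = 0.025
    swc_noise_sd: float = 0.015
    attenuation: float = 0.6     # fractional slope loss from first to last stage
    sal_ref: float = 2.0         # dS/m pivot for all salinity effects

    # --- spectra ---
    wavelength_start: int = 350
    wavelength_stop: int = 2500
    canopy_salinity_sd: float = 0.35  # dS/m perception noise on S2
    # broad response is relative to the local reflectance level (pigment loss
    # brightens the visible region, canopy drying darkens the LWIR)
    vis_response_rel: float = 0.10    # fractional increase per dS/m, 400-780 nm
    lwir_response_rel: float = 0.05   # fractional decrease per dS/m, 1100-2400 nm
    # narrow diagnostic features: (centre nm, fractional response per dS/m)
    informative_bands: tuple[tuple[float, float], ...] = (
        (745.0, -0.10), (1000.0, -0.10), (1180.0, -0.10), (2200.0, 0.06),
    )
    informative_width_nm: float = 12.0
    # per-band amplitude modulation across stages (phenology-dependent
    # sensitivity); spreads the salinity signal over several latent directions
    informative_stage_mod: tuple[tuple[float, ...], ...] = (
        (1.4, 1.2, 1.0, 0.8, 0.6),
        (0.6, 0.8, 1.0, 1.2, 1.4),
        (1.2, 0.7, 1.1, 0.8, 1.2),
        (1.0, 1.0, 1.0, 1.0, 1.0),
    )
    vis_stage_factor: tuple[float, ...] = (1.06, 1.00, 0.94, 1.02, 1.10)
    lwir_stage_factor: tuple[float, ...] = (0.96, 1.04, 1.00, 0.95, 0.90)
    # (sd, correlation length nm, relative): fine additive instrument noise
    # plus coarse smooth nuisance (canopy geometry / background variation)
    # that scales with the local reflectance level — strong on the NIR/SWIR
    # plateau, weak in the dark visible region — masking the broad salinity
    # response while the narrow informative bands stay readable
    noise_components: tuple[tuple[float, float, bool], ...] = (
        (0.010, 10.0, False),   # fine instrument noise
        (0.100, 120.0, True),   # canopy-structure wiggles, relative sd
        (0.100, 600.0, True),   # near-baseline drift (illumination/scatter)
    )

    def __post_init__(self):
        self.ec_layer_means = np.asarray(self.ec_layer_means, dtype=float)
        expected = (len(self.treatments), len(self.stages_das), 3)
        if self.ec_layer_means.shape != expected:
            raise ValueError(f"ec_layer_means must have shape {expected}")
        if np.any(self.ec_layer_means <= 0):
            raise ValueError("EC means must be positive")

    @property
    def n_samples(self) -> int:
        return len(self.treatments) * len(self.stages_das) * self.n_reps

    def wavelengths(self) -> np.ndarray:
        return np.arange(self.wavelength_start, self.wavelength_stop + 1, dtype=float)

    def stage_slope(self, base: float) -> np.ndarray:
        """Per-stage salinity slope with linear seasonal attenuation."""
        j = np.arange(len(self.stages_das))
        return base * (1.0 - self.attenuation * j / max(len(self.stages_das) - 1, 1))


def _seed_for(master_rng_or_seed, label: str):
    import zlib

    if isinstance(master_rng_or_seed, np.random.Generator):
        return master_rng_or_seed
    ss = np.random.SeedSequence([int(master_rng_or_seed), zlib.crc32(label.encode())])
    return np.random.default_rng(ss)


def generate_salinity(config: SyntheticConfig, seed=0) -> pd.DataFrame:
    """Per-record layered EC draws around the configured treatment means.

    Draws falling at or below ``ec_floor`` are redrawn (up to 20 attempts)
    and finally floored with a warning, so EC stays positive even under an
    aggressive scatter setting.
    """
    rng = _seed_for(seed, "salinity")
    rows = []
    resampled = 0
    for ti, trt in enumerate(config.treatments):
        for si, das in enumerate(config.stages_das):
            mu = config.ec_layer_means[ti, si]
            for rep in range(config.n_reps):
                ec = mu + rng.normal(0.0, config.ec_sd, size=3)
                for _ in range(5):
                    bad = ec <= config.ec_floor
                    if not bad.any():
                        break
                    resampled += int(bad.sum())
                    ec[bad] = mu[bad] + rng.normal(0.0, config.ec_sd, size=int(bad.sum()))
                ec = np.maximum(ec, config.ec_floor)
                rows.append(
                    {
                        "sample_id": f"{trt}-{das}-{rep + 1:02d}",
                        "treatment": trt,
                        "stage_das": das,
                        "rep": rep + 1,
                        "ec_0_20": ec[0],
                        "ec_20_40": ec[1],
                        "ec_40_60": ec[2],
                    }
                )
    if resampled:
        warnings.warn(
            f"{resampled} non-positive EC draws were resampled (floored after 5 "
            "attempts); consider a smaller ec_sd"
        )
    return pd.DataFrame(rows)


def generate_growth(config: SyntheticConfig, ec: pd.DataFrame, seed=0) -> pd.DataFrame:
    """Append H_cm, AGB_g, SWC_frac columns driven by root-zone salinity (S2)."""
    rng = _seed_for(seed, "growth")
    df = ec.copy()
    s2 = ((df["ec_0_20"] + df["ec_20_40"]) / 2.0).to_numpy()
    das = df["stage_das"].to_numpy(dtype=float)
    stage_idx = np.searchsorted(np.asarray(config.stages_das), das)
    dev = s2 - config.sal_ref
    n = len(df)

    h_slope = config.stage_slope(config.h_sal_slope)[stage_idx]
    das_eff = np.minimum(das, config.h_plateau_das)
    h_base = config.h_max * _sig((das_eff - config.h_mid_das) / config.h_tau)
    H = h_base - h_slope * dev + rng.normal(0.0, config.h_noise_sd, n)
    df["H_cm"] = np.maximum(H, 1.0)

    trt_idx = pd.Categorical(df["treatment"], categories=list(config.treatments)).codes
    t_peak = np.asarray(config.agb_peak_das)[trt_idx]
    agb_base = config.agb_max * _sig((das - config.agb_mid_das) / config.agb_tau)
    agb_base *= 1.0 - config.agb_decline * np.maximum(0.0, das - t_peak) / 38.0
    # suppression and scatter scale with the stage baseline, so the biomass-
    # salinity correlation is negative at every stage and attenuates cleanly
    agb_rel = config.stage_slope(config.agb_sal_rel)[stage_idx]
    AGB = agb_base * (1.0 - agb_rel * dev) + agb_base * config.agb_noise_cv * rng.normal(size=n)
    df["AGB_g"] = np.maximum(AGB, 0.1)

    swc_slope = config.stage_slope(config.swc_sal_slope)[stage_idx]
    SWC = (
        config.swc_start
        - config.swc_decline_per_das * (das - config.stages_das[0])
        - swc_slope * dev
        + rng.normal(0.0, config.swc_noise_sd, n)
    )
    df["SWC_frac"] = np.clip(SWC, 0.05, 0.95)
    return df


def _baseline_curve(wl, agb, swc, vis_factor, lwir_factor, agb_ref):
    """Vectorised vegetation reflectance baseline, (n, p)."""
    red_edge = _sig((wl - 715.0) / 15.0)
    decay = 1.0 - 0.35 * _sig((wl - 1350.0) / 180.0)
    vis_part = 0.03 + 0.045 * _gauss(wl, 550.0, 30.0)
    vis_part = vis_part[None, :] * vis_factor[:, None] * (1.0 - red_edge)[None, :]

    d1450 = np.clip(0.45 + 0.25 * swc, 0.0, 0.95)
    d1940 = np.clip(0.60 + 0.35 * swc, 0.0, 0.98)
    trough = (
        1.0
        - d1450[:, None] * _gauss(wl, 1450.0, 38.0)[None, :]
        - d1940[:, None] * _gauss(wl, 1940.0, 50.0)[None, :]
        - 0.05 * _gauss(wl, 1200.0, 40.0)[None, :]
    )
    plateau_amp = (0.46 + 0.0004 * (agb - agb_ref)) * lwir_factor
    plateau = plateau_amp[:, None] * (red_edge * decay)[None, :] * trough
    return vis_part + plateau


def generate_spectra(config: SyntheticConfig, samples: pd.DataFrame, seed=0):
    """Canopy reflectance for each record.

    Returns ``(wavelengths, reflectance, ec_canopy)`` where ``ec_canopy`` is
    the latent canopy-effective salinity each spectrum actually responded to.
    """
    rng = _seed_for(seed, "spectra")
    wl = config.wavelengths()
    n = len(samples)
    s2 = ((samples["ec_0_20"] + samples["ec_20_40"]) / 2.0).to_numpy()
    ec_canopy = s2 + rng.normal(0.0, config.canopy_salinity_sd, n)
    stage_idx = np.searchsorted(
        np.asarray(config.stages_das), samples["stage_das"].to_numpy()
    )
    vis_f = np.asarray(config.vis_stage_factor)[stage_idx]
    lwir_f = np.asarray(config.lwir_stage_factor)[stage_idx]
    agb = samples["AGB_g"].to_numpy(dtype=float)
    swc = samples["SWC_frac"].to_numpy(dtype=float)

    refl = _baseline_curve(wl, agb, swc, vis_f, lwir_f, agb_ref=0.7 * config.agb_max)
    dev = (ec_canopy - config.sal_ref)[:, None]
    vis_mask = _sig((wl - 400.0) / 15.0) * _sig((780.0 - wl) / 15.0)
    lwir_mask = _sig((wl - 1100.0) / 30.0) * _sig((2400.0 - wl) / 30.0)
    refl *= (
        1.0
        + config.vis_response_rel * dev * vis_mask[None, :]
        - config.lwir_response_rel * dev * lwir_mask[None, :]
    )
    for k, (center, amp) in enumerate(config.informative_bands):
        mods = config.informative_stage_mod
        mod = np.asarray(mods[k % len(mods)])[stage_idx][:, None] if mods else 1.0
        refl *= 1.0 + amp * mod * dev * _gauss(wl, center, config.informative_width_nm)[None, :]

    signal = refl.copy()
    for sd, corr_len, *rel in config.noise_components:
        if sd <= 0:
            continue
        relative = bool(rel[0]) if rel else False
        phi = np.exp(-1.0 / corr_len)
        burn = int(5 * corr_len)
        z = rng.standard_normal((n, wl.size + burn))
        noise = lfilter([sd * np.sqrt(1 - phi**2)], [1.0, -phi], z, axis=1)[:, burn:]
        refl += noise * signal if relative else noise
    return wl, np.clip(refl, 0.0, 1.2), ec_canopy


def generate_dataset(config: SyntheticConfig | None = None, seed: int = 0) -> Dataset:
    """Full draw: salinity -> growth -> spectra, as a :class:`Dataset`."""
    config = config or SyntheticConfig()
    ec = generate_salinity(config, seed)
    samples = generate_growth(config, ec, seed)
    wl, refl, ec_canopy = generate_spectra(config, samples, seed)
    samples = samples.copy()
    samples["ec_canopy"] = ec_canopy
    return Dataset(samples=samples, wavelengths=wl, reflectance=refl)


def write_dataset(ds: Dataset, outdir) -> None:
    """Emit samples.csv + spectra.csv accepted by the modelling layer."""
    ds.write(outdir)
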