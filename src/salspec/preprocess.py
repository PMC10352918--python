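"""Canopy reflectance preprocessing.

Raw canopy spectra arrive on a 1-nm grid spanning 350-2500 nm. Analysis uses
two representations:

* **R** — band-trimmed, Savitzky-Golay smoothed reflectance. The default trim
  removes the noisy instrument margins (350-399, 2401-2500 nm) and the two
  atmospheric water-vapour windows (1361-1489, 1811-1959 nm), leaving 1723
  bands in three contiguous segments.
* **FDR** — first-derivative reflectance (nm^-1), the wavelength derivative of
  the smoothed spectrum, computed per contiguous segment so that no filter
  window ever spans a trimmed gap.

Functions operate on a wavelength vector plus a values array whose last axis
is the band axis, so a whole sample matrix is processed in one call; the
:class:`Spectrum` wrapper provides the single-sample object view with
validation (raw reflectance must be finite, non-negative, and below 1.5 —
values in (1, 1.5] can occur through calibration-panel artefacts and are
tolerated with a warning).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.signal import savgol_filter

__all__ = [
    "DEFAULT_TRIM_WINDOWS",
    "Spectrum",
    "EmptySpectrumError",
    "SegmentTooShortError",
    "contiguous_segments",
    "trim_bands",
    "sg_smooth",
    "first_derivative",
    "bandwise_correlation",
]

#: Closed wavelength intervals [lo, hi] (nm) deleted by the default trim.
DEFAULT_TRIM_WINDOWS: tuple[tuple[int, int], ...] = (
    (350, 399),
    (1361, 1489),
    (1811, 1959),
    (2401, 2500),
)

REFLECTANCE_HARD_MAX = 1.5


class EmptySpectrumError(ValueError):
    """Raised when a trim removes every wavelength."""


class SegmentTooShortError(ValueError):
    """Raised when a contiguous segment is shorter than the filter window."""


def _normalize_windows(windows) -> list[tuple[float, float]]:
    """Sort and merge overlapping intervals."""
    ivs = sorted((float(lo), float(hi)) for lo, hi in windows)
    merged: list[list[float]] = []
    for lo, hi in ivs:
        if hi < lo:
            raise ValueError(f"window [{lo}, {hi}] has hi < lo")
        if merged and lo <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], hi)
        else:
            merged.append([lo, hi])
    return [(lo, hi) for lo, hi in merged]


def contiguous_segments(wavelengths: np.ndarray, step: float | None = None) -> list[slice]:
    """Slices of maximal runs with constant unit spacing.

    A gap is any spacing strictly larger than ``step`` (default: the smallest
    spacing present, normally 1 nm).
    """
    wl = np.asarray(wavelengths, dtype=float)
    if wl.size == 0:
        return []
    if wl.size == 1:
        return [slice(0, 1)]
    d = np.diff(wl)
    if np.any(d <= 0):
        raise ValueError("wavelength grid must be strictly increasing")
    if step is None:
        step = float(d.min())
    breaks = np.flatnonzero(d > step * 1.5)
    starts = np.concatenate([[0], breaks + 1])
    stops = np.concatenate([breaks + 1, [wl.size]])
    return [slice(int(a), int(b)) for a, b in zip(starts, stops)]


def trim_bands(wavelengths, values, windows=DEFAULT_TRIM_WINDOWS):
    """Delete every band falling inside any closed trim interval.

    Returns ``(wavelengths, values)`` with the band axis (last) filtered;
    relative order is preserved. Raises :class:`EmptySpectrumError` if nothing
    survives.
    """
    wl = np.asarray(wavelengths, dtype=float)
    vals = np.asarray(values, dtype=float)
    keep = np.ones(wl.shape, dtype=bool)
    for lo, hi in _normalize_windows(windows):
        keep &= ~((wl >= lo) & (wl <= hi))
    if not keep.any():
        raise EmptySpectrumError("trim windows removed every wavelength")
    return wl[keep], vals[..., keep]


def sg_smooth(wavelengths, values, window_pts: int = 13, polyorder: int = 2):
    """Savitzky-Golay smoothing, applied independently per contiguous segment.

    ``window_pts`` is the filter length in points (13 points = 13 nm on the
    native grid). Segment edges are handled by fitting the edge polynomial to
    the one-sided window (scipy's ``interp`` mode), so low-order polynomials
    are reproduced exactly everywhere. A segment shorter than the window
    raises :class:`SegmentTooShortError`.
    """
    wl = np.asarray(wavelengths, dtype=float)
    vals = np.asarray(values, dtype=float)
    if window_pts % 2 == 0 or window_pts <= polyorder:
        raise ValueError("window_pts must be odd and greater than polyorder")
    out = np.empty_like(vals)
    for seg in contiguous_segments(wl):
        if seg.stop - seg.start < window_pts:
            raise SegmentTooShortError(
                f"segment {wl[seg.start]:.0f}-{wl[seg.stop - 1]:.0f} nm has "
                f"{seg.stop - seg.start} points < window {window_pts}"
            )
        out[..., seg] = savgol_filter(
            vals[..., seg], window_pts, polyorder, axis=-1, mode="interp"
        )
    return out


def first_derivative(
    wavelengths,
    values,
    window_pts: int = 13,
    polyorder: int = 2,
    method: str = "savgol",
):
    """First-derivative reflectance (per nm), per contiguous segment.

    ``method="savgol"`` (default) uses the Savitzky-Golay derivative with the
    same window/order as the smoother, which keeps the noise behaviour of R
    and FDR consistent; ``method="gradient"`` uses central finite differences.
    Segments shorter than 3 points (or the window, for savgol) raise
    :class:`SegmentTooShortError`.
    """
    wl = np.asarray(wavelengths, dtype=float)
    vals = np.asarray(values, dtype=float)
    out = np.empty_like(vals)
    for seg in contiguous_segments(wl):
        npts = seg.stop - seg.start
        if npts < 3:
            raise SegmentTooShortError("derivative needs at least 3 points per segment")
        w = wl[seg]
        step = float(np.diff(w).mean())
        if method == "savgol":
            if npts < window_pts:
                raise SegmentTooShortError(
                    f"segment of {npts} points shorter than window {window_pts}"
                )
            out[..., seg] = savgol_filter(
                vals[..., seg], window_pts, polyorder, deriv=1, delta=step,
                axis=-1, mode="interp",
            )
        elif method == "gradient":
            out[..., seg] = np.gradient(vals[..., seg], w, axis=-1)
        else:
            raise ValueError(f"unknown derivative method {method!r}")
    return out


def bandwise_correlation(values_2d, target):
    """Per-band Pearson correlation between reflectance and a scalar target.

    Parameters
    ----------
    values_2d : (n_samples, n_bands) spectra on a common grid.
    target : (n_samples,) response (e.g. layer-averaged EC_1:5).

    Returns
    -------
    r : (n_bands,) correlations; bands with zero variance are NaN.
    best_idx : index of the band maximising ``|r|`` (NaNs excluded).
    r_best : correlation at that band.
    """
    X = np.asarray(values_2d, dtype=float)
    y = np.asarray(target, dtype=float).ravel()
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("values must be (n_samples, n_bands) aligned with target")
    if X.shape[0] < 3:
        raise ValueError("need at least 3 samples for a correlation")
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    sx = np.sqrt((Xc**2).sum(axis=0))
    sy = float(np.sqrt((yc**2).sum()))
    if sy == 0:
        raise ValueError("target has zero variance")
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Xc.T @ yc) / (sx * sy)
    r[sx == 0] = np.nan
    if np.all(np.isnan(r)):
        raise ValueError("every band has zero variance")
    best_idx = int(np.nanargmax(np.abs(r)))
    return r, best_idx, float(r[best_idx])


@dataclass
class Spectrum:
    """A single spectrum: wavelength grid (nm) plus values and a kind tag.

    ``kind`` is one of ``raw``, ``smoothed``, ``fdr``. Raw and smoothed values
    must be finite and non-negative; raw reflectance above 1 triggers a
    warning (calibration-panel artefact) and above 1.5 an error. FDR values
    may take any sign (units nm^-1).
    """

    wavelengths: np.ndarray
    values: np.ndarray
    kind: str = "raw"
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.wavelengths.shape != self.values.shape:
            raise ValueError("wavelengths and values must have equal length")
        if self.wavelengths.size and np.any(np.diff(self.wavelengths) <= 0):
            raise ValueError("wavelength grid must be strictly increasing")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("spectrum values must be finite")
        if self.kind in ("raw", "smoothed"):
            if np.any(self.values < 0):
                raise ValueError("reflectance must be non-negative")
            vmax = float(self.values.max(initial=0.0))
            if vmax > REFLECTANCE_HARD_MAX:
                raise ValueError(f"reflectance {vmax:.3f} exceeds {REFLECTANCE_HARD_MAX}")
            if vmax > 1.0:
                warnings.warn(
                    f"reflectance up to {vmax:.3f} > 1 tolerated (panel artefact)",
                    stacklevel=3,
                )
        elif self.kind != "fdr":
            raise ValueError(f"unknown spectrum kind {self.kind!r}")

    def trim(self, windows=DEFAULT_TRIM_WINDOWS) -> "Spectrum":
        wl, vals = trim_bands(self.wavelengths, self.values, windows)
        return replace(self, wavelengths=wl, values=vals)

    def smooth(self, window_pts: int = 13, polyorder: int = 2) -> "Spectrum":
        vals = sg_smooth(self.wavelengths, self.values, window_pts, polyorder)
        return replace(self, values=np.clip(vals, 0.0, None), kind="smoothed")

    def derivative(self, window_pts: int = 13, polyorder: int = 2, method: str = "savgol") -> "Spectrum":
        vals = first_derivative(self.wavelengths, self.values, window_pts, polyorder, method)
        return replace(self, values=vals, kind="fdr")

    def segments(self) -> list[slice]:
        return contiguous_segments(self.wavelengths)
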