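"""Replicate-based noise metrics and irradiance integration.

The central quantity is the per-pixel, per-band signal-to-noise ratio
estimated from sequential replicate images of an unchanging scene:

    SNR = μ_signal / σ_signal

with μ and σ the mean and sample standard deviation (n−1 denominator)
across replicates at one pixel and band.  Pixels where σ = 0 leave the SNR
undefined; they are masked and excluded from averages rather than mapped
to infinity.

Composite SNR averages the defined per-pixel-per-band values over a frame
(optionally ROI-restricted: the ROI is applied first, then averaged) and
over all wavelengths.  Unmixed SNR applies the same replicate statistics to
per-endmember abundance images after unmixing each replicate
independently.  The coefficient of variation (CV) summarizes
replicate-to-replicate stability of a fluorophore's ROI-mean total
emission.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datamodel import AcquisitionSeries, Roi, SpectralLibrary, total_emission_image, validate_series
from .unmix import unmix

__all__ = [
    "SnrMap", "snr_map", "composite_snr", "snr_per_band",
    "unmixed_snr", "roi_cv", "integrate_irradiance",
]


@dataclass
class SnrMap:
    """Per-pixel, per-band replicate SNR with its ingredients."""

    snr: np.ndarray  # (rows, cols, bands); NaN where undefined
    mean: np.ndarray
    sd: np.ndarray
    n_replicates: int
    undefined_mask: np.ndarray  # True where sd == 0


def _require_replicates(series: AcquisitionSeries) -> None:
    problems = validate_series(series)
    if problems:
        raise ValueError(f"invalid series: {problems}")
    if series.kind != "replicate":
        raise ValueError(f"replicate series required, got kind={series.kind!r}")


def _undefined(mu: np.ndarray, sd: np.ndarray) -> np.ndarray:
    # σ == 0 up to float rounding: identical replicates stored as floats can
    # leave a residual sd of order |mean|·eps, which is still "no variation"
    return sd <= np.abs(mu) * 1e-12


def snr_map(series: AcquisitionSeries) -> SnrMap:
    """Mean, sample SD and SNR across replicates at each pixel and band."""
    _require_replicates(series)
    stack = series.stack().astype(float)
    mu = stack.mean(axis=0)
    sd = stack.std(axis=0, ddof=1)
    undefined = _undefined(mu, sd)
    snr = np.full(mu.shape, np.nan)
    np.divide(mu, sd, out=snr, where=~undefined)
    return SnrMap(snr, mu, sd, len(series.cubes), undefined)


def _roi_mask(arr_shape, roi: Roi | None) -> np.ndarray:
    if roi is None:
        return np.ones(arr_shape[:2], dtype=bool)
    if roi.mask.shape != arr_shape[:2]:
        raise ValueError(f"ROI geometry {roi.mask.shape} does not match frame {arr_shape[:2]}")
    return roi.mask


def composite_snr(snrmap: SnrMap, roi: Roi | None = None) -> float:
    """Mean SNR over (ROI ∩ defined) pixels and all wavelength bands."""
    sel = _roi_mask(snrmap.snr.shape, roi)
    vals = snrmap.snr[sel]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValueError("no defined SNR values in the requested region")
    return float(vals.mean())


def snr_per_band(snrmap: SnrMap, roi: Roi | None = None) -> np.ndarray:
    """Per-band mean SNR over defined (ROI-restricted) pixels.

    Bands with no defined pixel come back NaN.
    """
    sel = _roi_mask(snrmap.snr.shape, roi)
    vals = snrmap.snr[sel]  # (n_sel, bands)
    if vals.size == 0:
        raise ValueError("ROI selects no pixels")
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # empty bands -> NaN
        return np.nanmean(vals, axis=0)


def unmixed_snr(series: AcquisitionSeries, library: SpectralLibrary,
                solver: str = "ols", roi: Roi | None = None) -> dict:
    """Per-endmember replicate SNR of unmixed abundance images.

    Each replicate is unmixed independently; μ/σ statistics are taken over
    replicates per pixel per endmember and averaged over (ROI ∩ defined).
    """
    _require_replicates(series)
    stacks = np.stack([unmix(c, library, solver).abundances for c in series.cubes], axis=0)
    mu = stacks.mean(axis=0)
    sd = stacks.std(axis=0, ddof=1)
    sel = _roi_mask(mu.shape, roi)
    out = {}
    for i, name in enumerate(library.names):
        m, s = mu[:, :, i][sel], sd[:, :, i][sel]
        defined = ~_undefined(m, s)
        if not defined.any():
            out[name] = float("nan")
        else:
            out[name] = float((m[defined] / s[defined]).mean())
    return out


def roi_cv(series: AcquisitionSeries, roi: Roi) -> float:
    """Coefficient of variation of ROI-mean total emission across replicates.

    One scalar per replicate (the mean total emission inside the ROI);
    CV = sample SD / mean of those scalars.
    """
    _require_replicates(series)
    roi.check_against(series.cubes[0])
    means = np.array([total_emission_image(c)[roi.mask].mean() for c in series.cubes])
    m = means.mean()
    if m == 0:
        raise ValueError("ROI mean total emission is zero; CV undefined")
    return float(means.std(ddof=1) / m)


def integrate_irradiance(spectrum_table: np.ndarray, center_nm: float,
                         halfwidth_nm: float) -> float:
    """Trapezoidal integral of irradiance over [center − hw, center + hw].

    ``spectrum_table`` is an (n, 2) wavelength/irradiance table with
    strictly increasing wavelengths covering the window (an excitation
    filter band ± 40 nm, or a 10 nm window around a laser line).  The
    window endpoints are interpolated onto the table so partial intervals
    integrate exactly.
    """
    table = np.asarray(spectrum_table, dtype=float)
    wl, irr = table[:, 0], table[:, 1]
    lo, hi = center_nm - halfwidth_nm, center_nm + halfwidth_nm
    if lo < wl[0] or hi > wl[-1]:
        raise ValueError(
            f"integration window {lo:g}-{hi:g} nm outside table support {wl[0]:g}-{wl[-1]:g} nm"
        )
    inside = (wl > lo) & (wl < hi)
    xs = np.concatenate(([lo], wl[inside], [hi]))
    ys = np.concatenate(([np.interp(lo, wl, irr)], irr[inside], [np.interp(hi, wl, irr)]))
    return float(np.trapezoid(ys, xs))
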