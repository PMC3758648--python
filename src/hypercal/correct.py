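"""Flat spectral correction and background subtraction.

A widefield hyperspectral system attenuates emission in a
wavelength-dependent way (optics, tunable filter, detector QE).  The
attenuation is measured with a NIST-traceable lamp: the system's spectral
transfer function is

    TF(λ) = (I_bright(λ) − I_dark(λ)) / I_lamp(λ)

and its reciprocal CC(λ) = 1/TF(λ) is the correction coefficient.  Raw
cubes are corrected per pixel and band as

    I_corrected(λ) = max(0, I_raw(λ) − I_dark(λ)) · CC(λ)

Negative dark-subtracted residuals are noise and are clamped to zero; the
clamp count is recorded in provenance.  Confocal systems with calibrated
detectors skip the flat correction and use plain background subtraction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .datamodel import Roi, SpectralCube, WavelengthAxis

__all__ = [
    "CalibrationSet", "CorrectionCoefficient",
    "calibration_from_cubes", "transfer_function", "apply_correction",
    "background_subtract", "lamp_on_axis",
]

log = logging.getLogger(__name__)


@dataclass
class CalibrationSet:
    """Dark, bright and lamp spectra on the cube's wavelength axis.

    Spectra are usually per-band vectors obtained by spatially averaging
    the calibration cubes; per-pixel (rows × cols × bands) dark/bright
    frames are also accepted for spatially non-uniform response.
    """

    dark_spectrum: np.ndarray
    bright_spectrum: np.ndarray
    lamp_spectrum: np.ndarray
    axis: WavelengthAxis
    flags: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.dark_spectrum = np.asarray(self.dark_spectrum, dtype=float)
        self.bright_spectrum = np.asarray(self.bright_spectrum, dtype=float)
        self.lamp_spectrum = np.asarray(self.lamp_spectrum, dtype=float)
        n = self.axis.n_bands
        for label, vec in (("dark", self.dark_spectrum), ("bright", self.bright_spectrum)):
            if vec.shape[-1] != n:
                raise ValueError(f"{label} spectrum has {vec.shape[-1]} bands, axis has {n}")
        if self.lamp_spectrum.ndim != 1 or self.lamp_spectrum.shape[0] != n:
            raise ValueError(f"lamp spectrum must be a {n}-band vector")
        if np.any(self.lamp_spectrum <= 0):
            bad = self.axis.centers[self.lamp_spectrum <= 0]
            raise ValueError(f"lamp irradiance must be strictly positive; non-positive at {bad} nm")
        if np.any(self.bright_spectrum < self.dark_spectrum):
            self.flags.append("bright < dark at some bands: non-physical transfer function")


def calibration_from_cubes(dark: SpectralCube, bright: SpectralCube,
                           lamp_spectrum: np.ndarray, reduce: str = "mean") -> CalibrationSet:
    """Reduce dark/bright calibration cubes to a calibration set.

    ``reduce="mean"`` spatially averages each calibration cube to a
    per-band spectrum (the default estimator); ``reduce="pixel"`` keeps
    the full frames for a per-pixel correction.
    """
    if not dark.axis.matches(bright.axis):
        raise ValueError("dark and bright cubes are on different wavelength axes")
    if reduce == "mean":
        d = dark.data.mean(axis=(0, 1))
        b = bright.data.mean(axis=(0, 1))
    elif reduce == "pixel":
        d, b = dark.data, bright.data
    else:
        raise ValueError(f"unknown reduce mode {reduce!r}")
    return CalibrationSet(d, b, np.asarray(lamp_spectrum, dtype=float), dark.axis)


@dataclass
class CorrectionCoefficient:
    """Transfer function TF(λ) and its reciprocal CC(λ)."""

    tf: np.ndarray
    cc: np.ndarray
    axis: WavelengthAxis


def transfer_function(cal: CalibrationSet) -> CorrectionCoefficient:
    """TF(λ) = (bright − dark)/lamp; the correction coefficient is 1/TF.

    Bands where TF ≤ 0 leave the correction undefined; rather than
    interpolating over them (which would fabricate instrument response)
    the calibration is rejected with the offending bands named.
    """
    tf = (cal.bright_spectrum - cal.dark_spectrum) / cal.lamp_spectrum
    bad = tf <= 0
    if bad.ndim > 1:
        bad = bad.any(axis=tuple(range(bad.ndim - 1)))
    if np.any(bad):
        bands = ", ".join(f"{w:g}" for w in cal.axis.centers[bad])
        raise ValueError(
            f"transfer function is non-positive at {int(bad.sum())} band(s): {bands} nm; "
            "correction is undefined there"
        )
    return CorrectionCoefficient(tf, 1.0 / tf, cal.axis)


def apply_correction(raw: SpectralCube, cal: CalibrationSet,
                     coeff: CorrectionCoefficient | None = None) -> SpectralCube:
    """Dark-subtract, clamp at zero, and multiply by CC(λ) per pixel/band."""
    if not raw.axis.matches(cal.axis):
        raise ValueError("raw cube and calibration are on different wavelength axes")
    if coeff is None:
        coeff = transfer_function(cal)
    residual = raw.data - cal.dark_spectrum
    n_clamped = int(np.count_nonzero(residual < 0))
    if n_clamped:
        log.info("apply_correction: clamped %d negative dark-subtracted values", n_clamped)
    corrected = np.clip(residual, 0, None) * coeff.cc
    return raw.with_data(
        corrected,
        corrected=True,
        clamped_values=n_clamped,
        calibration_flags=list(cal.flags),
    )


def background_subtract(cube: SpectralCube, background) -> SpectralCube:
    """Subtract a per-band background spectrum, clamping at zero.

    ``background`` is either a per-band vector or an ROI over a blank
    region of the cube, in which case the background spectrum is the
    pixel-averaged spectrum inside the ROI.  This is the only correction
    applied to confocal data, whose detector is already calibrated.
    """
    if isinstance(background, Roi):
        background.check_against(cube)
        spectrum = cube.data[background.mask].mean(axis=0)
    else:
        spectrum = np.asarray(background, dtype=float)
        if spectrum.shape != (cube.axis.n_bands,):
            raise ValueError(
                f"background spectrum must have {cube.axis.n_bands} bands, got shape {spectrum.shape}"
            )
    residual = cube.data - spectrum
    n_clamped = int(np.count_nonzero(residual < 0))
    if n_clamped:
        log.info("background_subtract: clamped %d negative values", n_clamped)
    return cube.with_data(np.clip(residual, 0, None),
                          background_subtracted=True, clamped_values=n_clamped)


def lamp_on_axis(lamp_table: np.ndarray, axis: WavelengthAxis) -> np.ndarray:
    """Linearly interpolate a (wavelength, irradiance) table onto the axis.

    The table must cover the full axis; extrapolation would invent lamp
    output where none was certified.
    """
    table = np.asarray(lamp_table, dtype=float)
    wl, irr = table[:, 0], table[:, 1]
    if axis.centers[0] < wl[0] or axis.centers[-1] > wl[-1]:
        raise ValueError(
            f"lamp table covers {wl[0]:g}-{wl[-1]:g} nm but the axis needs "
            f"{axis.centers[0]:g}-{axis.centers[-1]:g} nm"
        )
    return np.interp(axis.centers, wl, irr)
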