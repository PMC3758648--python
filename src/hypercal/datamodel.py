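"""Core containers for hyperspectral microscopy data.

A hyperspectral acquisition is a cube of intensities — two spatial axes and
one emission-wavelength axis — plus the wavelength grid it was sampled on.
Everything downstream (correction, library building, unmixing, SNR and
bleaching analysis) operates on these containers.

Conventions used throughout the package:

* images are row-major, pixel (0, 0) at the top-left, 0-based indices;
* band index 0 is the shortest wavelength;
* the wavelength axis is defined by band *centers*; bandwidth, when known,
  is metadata only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "WavelengthAxis",
    "SpectralCube",
    "AcquisitionSeries",
    "SpectralLibrary",
    "Roi",
    "make_wavelength_axis",
    "validate_series",
    "total_emission_image",
]


@dataclass(frozen=True)
class WavelengthAxis:
    """A uniform grid of emission band centers, in nanometres."""

    start_nm: float
    stop_nm: float
    step_nm: float
    centers: np.ndarray = field(repr=False)

    @property
    def n_bands(self) -> int:
        return len(self.centers)

    def matches(self, other: "WavelengthAxis") -> bool:
        """True when two axes describe the same band grid."""
        return self.n_bands == other.n_bands and np.allclose(
            self.centers, other.centers, rtol=0, atol=1e-9
        )

    def index_of(self, wavelength_nm: float) -> int:
        """Index of the band whose center is nearest to ``wavelength_nm``."""
        return int(np.argmin(np.abs(self.centers - wavelength_nm)))


def make_wavelength_axis(start_nm: float, stop_nm: float, step_nm: float) -> WavelengthAxis:
    """Build a wavelength axis with inclusive endpoints.

    The span (stop − start) must be an exact nonnegative multiple of the
    step, so that both endpoints fall on band centers.  For example a
    462–648 nm range at a 6 nm increment gives 32 bands.
    """
    if step_nm <= 0:
        raise ValueError(f"step_nm must be positive, got {step_nm}")
    span = stop_nm - start_nm
    if span < 0:
        raise ValueError(f"stop_nm ({stop_nm}) must be >= start_nm ({start_nm})")
    n_steps = span / step_nm
    k = round(n_steps)
    if abs(n_steps - k) > 1e-9:
        raise ValueError(
            "band count is not integral: "
            f"(stop_nm={stop_nm} - start_nm={start_nm}) / step_nm={step_nm} "
            f"= {n_steps} is not a whole number of bands"
        )
    centers = start_nm + step_nm * np.arange(k + 1, dtype=float)
    # pin the endpoints exactly against accumulated float error
    centers[-1] = stop_nm
    return WavelengthAxis(float(start_nm), float(stop_nm), float(step_nm), centers)


@dataclass
class SpectralCube:
    """One hyperspectral image: intensities on rows × cols × bands.

    ``bit_depth`` records the detector digitization (e.g. 12 for a
    multi-anode PMT, 16 for an EMCCD).  Raw cubes live in
    [0, 2**bit_depth − 1]; corrected cubes may exceed that ceiling but
    stay nonnegative.  ``meta`` carries free-form provenance (seeds,
    calibration identifiers, clamp counts).
    """

    data: np.ndarray
    axis: WavelengthAxis
    bit_depth: int = 16
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"cube data must be 3-D (rows, cols, bands), got shape {self.data.shape}")
        if self.data.shape[2] != self.axis.n_bands:
            raise ValueError(
                f"band dimension ({self.data.shape[2]}) does not match "
                f"wavelength axis ({self.axis.n_bands} bands)"
            )

    @property
    def shape(self) -> tuple:
        return self.data.shape

    @property
    def n_rows(self) -> int:
        return self.data.shape[0]

    @property
    def n_cols(self) -> int:
        return self.data.shape[1]

    def check(self, raw: bool = True) -> list:
        """Return a list of invariant violations (empty when valid)."""
        problems = []
        if np.any(self.data < 0):
            problems.append("negative intensities present")
        if raw:
            ceiling = 2 ** self.bit_depth - 1
            if np.any(self.data > ceiling):
                problems.append(f"intensities exceed the {self.bit_depth}-bit ceiling ({ceiling})")
        return problems

    def with_data(self, data: np.ndarray, **meta_updates) -> "SpectralCube":
        """Copy carrying new data and merged provenance."""
        meta = dict(self.meta)
        meta.update(meta_updates)
        return SpectralCube(np.asarray(data), self.axis, self.bit_depth, meta)

    def pixel_spectra(self) -> np.ndarray:
        """Flattened (n_pixels, n_bands) view of the cube."""
        return self.data.reshape(-1, self.axis.n_bands)


@dataclass
class AcquisitionSeries:
    """An ordered set of same-geometry cubes.

    ``kind`` is ``"replicate"`` for sequential images of an unchanging
    scene (the basis of SNR estimation, which needs at least two cubes)
    or ``"timeseries"`` for a bleaching run, in which case ``times_s``
    gives each cube's acquisition time in seconds.
    """

    cubes: list
    kind: str
    times_s: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.times_s is not None:
            self.times_s = np.asarray(self.times_s, dtype=float)

    def __len__(self) -> int:
        return len(self.cubes)

    def stack(self) -> np.ndarray:
        """(n_cubes, rows, cols, bands) array of all member cubes."""
        return np.stack([c.data for c in self.cubes], axis=0)

    def mean_cube(self) -> SpectralCube:
        """Pixelwise mean across member cubes (replicate averaging)."""
        first = self.cubes[0]
        return SpectralCube(
            self.stack().mean(axis=0), first.axis, first.bit_depth,
            {"averaged_over": len(self.cubes)},
        )


def validate_series(series: AcquisitionSeries) -> list:
    """Report every violated series invariant; an empty list means valid.

    Validation never raises: the report is the result.
    """
    report: list = []
    if series.kind not in ("replicate", "timeseries"):
        report.append(f"unknown series kind {series.kind!r}")
    if not series.cubes:
        report.append("series has no cubes")
        return report
    first = series.cubes[0]
    for i, cube in enumerate(series.cubes[1:], start=1):
        if cube.data.shape != first.data.shape:
            report.append(f"cube {i} geometry {cube.data.shape} differs from cube 0 {first.data.shape}")
        if not cube.axis.matches(first.axis):
            report.append(f"cube {i} wavelength axis differs from cube 0")
    if series.kind == "replicate" and len(series.cubes) < 2:
        report.append("replicate series needs >=2 cubes")
    if series.kind == "timeseries":
        if series.times_s is None:
            report.append("timeseries requires times_s")
        else:
            if len(series.times_s) != len(series.cubes):
                report.append(
                    f"times_s length ({len(series.times_s)}) does not match cube count ({len(series.cubes)})"
                )
            if len(series.times_s) > 1 and not np.all(np.diff(series.times_s) > 0):
                report.append("times not strictly increasing")
    elif series.times_s is not None:
        report.append("times_s given for a replicate series")
    return report


def total_emission_image(cube: SpectralCube) -> np.ndarray:
    """Per-pixel total fluorescence emission: the sum over all bands."""
    return cube.data.sum(axis=2)


@dataclass
class SpectralLibrary:
    """Named endmember spectra on a shared wavelength axis.

    ``spectra`` is (n_endmembers, n_bands).  ``normalization`` records how
    the spectra are scaled: ``raw`` (as measured), ``peak1`` (maximum band
    = 1, so unmixed abundances are in peak-intensity units) or ``area1``
    (band sum = 1).
    """

    names: list
    spectra: np.ndarray
    axis: WavelengthAxis
    normalization: str = "raw"

    def __post_init__(self) -> None:
        self.spectra = np.atleast_2d(np.asarray(self.spectra, dtype=float))
        if len(self.names) != self.spectra.shape[0]:
            raise ValueError("one name per spectrum required")
        if len(set(self.names)) != len(self.names):
            raise ValueError(f"endmember names must be unique, got {self.names}")
        if self.spectra.shape[1] != self.axis.n_bands:
            raise ValueError(
                f"spectra length ({self.spectra.shape[1]}) does not match axis ({self.axis.n_bands} bands)"
            )
        if np.any(self.spectra < 0):
            raise ValueError("endmember spectra must be nonnegative")
        zero = ~self.spectra.any(axis=1)
        if zero.any():
            bad = [n for n, z in zip(self.names, zero) if z]
            raise ValueError(f"all-zero endmember spectra: {bad}")

    @property
    def n_endmembers(self) -> int:
        return self.spectra.shape[0]

    @property
    def matrix(self) -> np.ndarray:
        """(n_bands, n_endmembers) mixing matrix, one endmember per column."""
        return self.spectra.T

    def spectrum(self, name: str) -> np.ndarray:
        return self.spectra[self.names.index(name)]

    def normalized(self, mode: str) -> "SpectralLibrary":
        """Return a copy scaled to the requested normalization."""
        if mode == "raw" or mode == self.normalization:
            return SpectralLibrary(list(self.names), self.spectra.copy(), self.axis, self.normalization)
        if self.normalization != "raw":
            raise ValueError(
                f"cannot renormalize a {self.normalization} library to {mode}; rebuild from raw spectra"
            )
        if mode == "peak1":
            scale = self.spectra.max(axis=1, keepdims=True)
        elif mode == "area1":
            scale = self.spectra.sum(axis=1, keepdims=True)
        else:
            raise ValueError(f"unknown normalization {mode!r} (expected raw, peak1 or area1)")
        return SpectralLibrary(list(self.names), self.spectra / scale, self.axis, mode)


@dataclass
class Roi:
    """A boolean region-of-interest mask over an image frame."""

    mask: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError("ROI mask must be 2-D")
        if not self.mask.any():
            raise ValueError(f"ROI {self.label!r} has no pixels")

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())

    def check_against(self, cube: SpectralCube) -> None:
        if self.mask.shape != cube.data.shape[:2]:
            raise ValueError(
                f"ROI geometry {self.mask.shape} does not match cube frame {cube.data.shape[:2]}"
            )

    @classmethod
    def square(cls, frame_shape: Sequence[int], side: int = 30,
               top_left: tuple | None = None, label: str = "") -> "Roi":
        """Axis-aligned square ROI; centered in the frame by default."""
        rows, cols = frame_shape
        if side > rows or side > cols:
            raise ValueError(f"square side {side} exceeds frame {frame_shape}")
        if top_left is None:
            top_left = ((rows - side) // 2, (cols - side) // 2)
        r0, c0 = top_left
        mask = np.zeros((rows, cols), dtype=bool)
        mask[r0:r0 + side, c0:c0 + side] = True
        return cls(mask, label or f"square{side}")

    @classmethod
    def full(cls, frame_shape: Sequence[int], label: str = "full") -> "Roi":
        return cls(np.ones(tuple(frame_shape), dtype=bool), label)
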