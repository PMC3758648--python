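"""Spike-in (theoretical sensitivity/specificity) study.

A known endmember spectrum — typically GFP — is added post-acquisition at
graded peak intensities to a small square region of a control cube that
contains no target signal (e.g. pure autofluorescence).  Unmixing each
spiked cube measures the response of the linear unmixing chain to
increasing single-component signal in the presence of the background:

* sensitivity — the slope of mean ROI abundance versus added peak
  intensity (ideal response: slope 1 when the spiked spectrum equals the
  library entry in peak-normalized units);
* specificity — a detection threshold is set at a quantile of the
  zero-added ROI abundance distribution (nearest-rank estimator) and
  pixels across the whole image whose abundance strictly exceeds it are
  counted as positive; positives outside the spiked region are false
  positives.

Cubes from detectors of different bit depths are first linearly rescaled
to a common depth so intensity levels are comparable across systems.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .datamodel import Roi, SpectralCube, SpectralLibrary
from .unmix import unmix

__all__ = [
    "SpikeInSpec", "SensitivityReport", "nearest_rank_quantile",
    "rescale_to_common_depth", "add_spikein", "classify_positives",
    "run_sensitivity",
]

DEFAULT_LEVELS = tuple(range(0, 1001, 100))


def nearest_rank_quantile(values, q: float) -> float:
    """Nearest-rank quantile: the smallest sample value whose cumulative
    fraction is ≥ q (rank ⌈q·n⌉ of the ascending order statistics).

    Distribution-free and exact on small samples; e.g. on the values
    1..900 at q = 0.985 the rank is ⌈886.5⌉ = 887 and the quantile is 887.
    """
    if not 0.0 < q < 1.0:
        raise ValueError(f"quantile must lie in (0, 1), got {q}")
    v = np.sort(np.asarray(values).ravel())
    if v.size == 0:
        raise ValueError("empty sample")
    rank = math.ceil(q * v.size)
    return float(v[rank - 1])


def rescale_to_common_depth(cube: SpectralCube, target_bits: int = 16) -> SpectralCube:
    """Linearly map a cube's intensity range onto a common bit depth.

    Multiplies by (2^target − 1)/(2^source − 1), so 0 maps to 0 and a
    full-scale value maps to full scale (4095 at 12 bits → 65535 at 16).
    """
    factor = (2 ** target_bits - 1) / (2 ** cube.bit_depth - 1)
    out = cube.with_data(cube.data * factor, rescaled_from_bits=cube.bit_depth)
    out.bit_depth = target_bits
    return out


def add_spikein(cube: SpectralCube, spectrum: np.ndarray, roi: Roi,
                peak_intensity: float, anchor: str = "peak") -> SpectralCube:
    """Add a scaled endmember spectrum to every pixel inside the ROI.

    The spectrum is scaled so its maximum band equals ``peak_intensity``
    (``anchor="peak"``; ``anchor="area"`` scales the band sum instead).
    Pixels outside the ROI are untouched, and a level of 0 returns an
    identical cube.
    """
    spectrum = np.asarray(spectrum, dtype=float)
    if spectrum.shape != (cube.axis.n_bands,):
        raise ValueError(f"spike spectrum must have {cube.axis.n_bands} bands")
    if peak_intensity < 0:
        raise ValueError("peak_intensity must be >= 0")
    roi.check_against(cube)
    norm = spectrum.max() if anchor == "peak" else spectrum.sum()
    if anchor not in ("peak", "area"):
        raise ValueError(f"anchor must be 'peak' or 'area', got {anchor!r}")
    if norm <= 0:
        raise ValueError("cannot spike an all-zero spectrum")
    data = cube.data.astype(float).copy()
    data[roi.mask] += (peak_intensity / norm) * spectrum
    return cube.with_data(data, spiked_peak=peak_intensity)


def classify_positives(abundance_image: np.ndarray, threshold: float,
                       inclusive: bool = True) -> tuple:
    """Threshold an abundance image into positive/negative pixels.

    Returns ``(boolean image, count, percentage of all pixels)``.  By
    default the comparison is inclusive (abundance ≥ threshold counts as
    positive).
    """
    if not np.isfinite(threshold):
        raise ValueError(f"threshold must be finite, got {threshold}")
    img = np.asarray(abundance_image)
    positive = img >= threshold if inclusive else img > threshold
    count = int(positive.sum())
    return positive, count, 100.0 * count / img.size


@dataclass
class SpikeInSpec:
    """Parameters of one spike-in study.

    ``levels`` must include 0 — the null level whose ROI abundance
    distribution defines the detection threshold.  ``quantile`` defaults to
    0.985; ``scale_to_bits`` rescales the control to a common depth first
    (None skips rescaling).
    """

    target: str
    roi: Roi | None = None  # default: centered 30x30 square
    levels: tuple = DEFAULT_LEVELS
    quantile: float = 0.985
    scale_to_bits: int | None = 16
    anchor: str = "peak"

    def __post_init__(self):
        levels = tuple(float(l) for l in self.levels)
        if 0.0 not in levels:
            raise ValueError("spike-in levels must include 0 (the null level)")
        if any(l < 0 for l in levels):
            raise ValueError("spike-in levels must be >= 0")
        if not 0.0 < self.quantile < 1.0:
            raise ValueError(f"quantile must lie in (0, 1), got {self.quantile}")
        self.levels = levels


@dataclass
class SensitivityReport:
    """Everything the spike-in study measures."""

    target: str
    levels: np.ndarray
    roi_abundances: np.ndarray  # (n_levels, n_roi_pixels)
    mean_roi_abundance: np.ndarray  # (n_levels,)
    slope: float
    intercept: float
    threshold: float
    quantile: float
    positive_counts: np.ndarray  # whole-image counts per level
    false_positive_fraction: np.ndarray  # out-of-ROI positives / total pixels
    n_total_pixels: int
    n_roi_pixels: int

    def summary(self) -> str:
        lines = [
            f"Spike-in sensitivity study: target {self.target!r}, "
            f"{self.n_roi_pixels}-pixel ROI in {self.n_total_pixels} pixels",
            f"detection threshold: {self.threshold:.6g} abundance units "
            f"({self.quantile:.4g} quantile at level 0)",
            f"response: abundance = {self.slope:.4f} x added + {self.intercept:.4g}",
            f"{'added':>8} {'mean abundance':>15} {'positives':>10} {'FP %':>8}",
        ]
        for lev, ab, cnt, fp in zip(self.levels, self.mean_roi_abundance,
                                    self.positive_counts, self.false_positive_fraction):
            lines.append(f"{lev:>8g} {ab:>15.4g} {cnt:>10d} {100 * fp:>8.4f}")
        return "\n".join(lines)

    def plot(self, ax=None):
        """Mean ROI abundance vs added signal, with the linear fit."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.levels, self.mean_roi_abundance, "o", label="measured")
        xs = np.linspace(self.levels.min(), self.levels.max(), 50)
        ax.plot(xs, self.slope * xs + self.intercept, "-",
                label=f"fit: slope {self.slope:.3f}")
        ax.set_xlabel(f"{self.target} signal added (peak intensity, A.U.)")
        ax.set_ylabel(f"unmixed {self.target} abundance")
        ax.legend()
        return ax


def run_sensitivity(control: SpectralCube, library: SpectralLibrary,
                    spec: SpikeInSpec, solver: str = "ols") -> SensitivityReport:
    """Run the full spike-in study against a target-free control cube.

    For each level: spike, unmix, and record the target-abundance
    distribution inside the ROI.  The detection threshold is the
    nearest-rank quantile of the level-0 ROI abundances; at every level,
    whole-image pixels whose abundance strictly exceeds the threshold are
    counted as positive (the threshold itself, being the largest null value
    deemed negative, is classed negative), and positives outside the ROI
    are false positives.
    """
    if spec.target not in library.names:
        raise ValueError(f"target {spec.target!r} not in library {library.names}")
    if spec.scale_to_bits is not None and control.bit_depth != spec.scale_to_bits:
        control = rescale_to_common_depth(control, spec.scale_to_bits)
    roi = spec.roi if spec.roi is not None else Roi.square(control.data.shape[:2], 30, label="spike")
    roi.check_against(control)
    spectrum = library.spectrum(spec.target)

    levels = np.asarray(spec.levels, dtype=float)
    roi_abund = []
    images = []
    for level in levels:
        spiked = add_spikein(control, spectrum, roi, level, spec.anchor)
        result = unmix(spiked, library, solver)
        img = result.abundance(spec.target)
        images.append(img)
        roi_abund.append(img[roi.mask])
    roi_abund = np.asarray(roi_abund)  # (n_levels, n_roi)
    mean_ab = roi_abund.mean(axis=1)

    null_idx = int(np.where(levels == 0)[0][0])
    threshold = nearest_rank_quantile(roi_abund[null_idx], spec.quantile)

    slope, intercept = np.polyfit(levels, mean_ab, 1)

    n_total = images[0].size
    counts, fp_frac = [], []
    for img in images:
        positive, count, _ = classify_positives(img, threshold, inclusive=False)
        counts.append(count)
        fp_frac.append(float(positive[~roi.mask].sum()) / n_total)
    return SensitivityReport(
        target=spec.target,
        levels=levels,
        roi_abundances=roi_abund,
        mean_roi_abundance=mean_ab,
        slope=float(slope),
        intercept=float(intercept),
        threshold=threshold,
        quantile=spec.quantile,
        positive_counts=np.asarray(counts, dtype=int),
        false_positive_fraction=np.asarray(fp_frac),
        n_total_pixels=int(n_total),
        n_roi_pixels=roi.n_pixels,
    )
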