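"""Endmember spectral-library construction.

Libraries are built from single-fluorophore control acquisitions (a
GFP-expressing monolayer, a Hoechst-stained control, unlabeled tissue for
autofluorescence): the total-emission image is thresholded to an ROI of
bright pixels and the endmember spectrum is the pixel-averaged spectrum
inside that ROI.

The threshold is a quantile of the total-emission image (default 0.95),
which is reproducible across exposure scales where an absolute count
threshold is not; Otsu's method is offered as an alternative.
"""

from __future__ import annotations

import numpy as np

from .datamodel import Roi, SpectralCube, SpectralLibrary, WavelengthAxis, total_emission_image

__all__ = ["extract_endmember", "build_library", "condition_report"]


def extract_endmember(cube: SpectralCube, threshold_quantile: float = 0.95,
                      method: str = "quantile") -> tuple:
    """Recover a pure endmember spectrum from a control cube.

    Pixels whose total emission is at or above the threshold form the ROI;
    the endmember spectrum is the mean spectrum over those pixels.  The
    cube should already be background-subtracted (and flat-corrected on a
    widefield system).  Returns ``(spectrum, roi)``.
    """
    total = total_emission_image(cube)
    if method == "quantile":
        if not 0.0 < threshold_quantile < 1.0:
            raise ValueError(f"threshold_quantile must lie in (0, 1), got {threshold_quantile}")
        thr = np.quantile(total, threshold_quantile)
    elif method == "otsu":
        from skimage.filters import threshold_otsu

        thr = threshold_otsu(total)
    else:
        raise ValueError(f"unknown threshold method {method!r}")
    mask = total >= thr
    if not mask.any():
        raise ValueError(
            f"threshold at the {threshold_quantile} quantile leaves an empty ROI"
        )
    roi = Roi(mask, label=f"{method}>={thr:g}")
    spectrum = cube.data[mask].mean(axis=0)
    return spectrum, roi


def build_library(endmembers, axis: WavelengthAxis,
                  normalization: str = "raw") -> SpectralLibrary:
    """Assemble named (name, spectrum) pairs into a library.

    ``normalization``: ``raw`` keeps measured intensities, ``peak1``
    scales each spectrum to unit maximum (abundances then come out in
    peak-intensity units), ``area1`` to unit band sum.
    """
    names = [name for name, _ in endmembers]
    spectra = np.stack([np.asarray(s, dtype=float) for _, s in endmembers])
    lib = SpectralLibrary(names, spectra, axis, "raw")
    return lib.normalized(normalization)


def condition_report(library: SpectralLibrary) -> dict:
    """Diagnose near-collinear endmembers before they poison unmixing.

    Reports pairwise cosine similarities and the condition number of the
    mixing matrix.  Spectrally similar endmembers (cosine near 1) make the
    least-squares problem ill-conditioned and abundance estimates noisy.
    """
    if library.n_endmembers < 2:
        raise ValueError("condition report needs at least 2 endmembers")
    s = library.spectra
    norms = np.linalg.norm(s, axis=1)
    unit = s / norms[:, None]
    cosine = unit @ unit.T
    cond = float(np.linalg.cond(library.matrix))
    flags = []
    k = library.n_endmembers
    for i in range(k):
        for j in range(i + 1, k):
            if cosine[i, j] > 0.99:
                flags.append(
                    f"endmembers {library.names[i]!r} and {library.names[j]!r} are nearly "
                    f"collinear (cosine {cosine[i, j]:.4f})"
                )
    if not np.isfinite(cond) or cond > 1e8:
        flags.append(f"library matrix is ill-conditioned (condition number {cond:.3g})")
    return {
        "names": list(library.names),
        "cosine": cosine,
        "condition_number": cond,
        "flags": flags,
    }
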