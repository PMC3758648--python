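"""Per-pixel linear spectral unmixing.

Each measured pixel spectrum x (n bands) is modelled as a linear mixture
of the library endmembers S (n × k): x ≈ S·a.  The abundance vector a is
estimated per pixel by ordinary least squares (the default, matching the
common behaviour of ENVI-style unmixing) or nonnegative least squares
(negative abundances being non-physical).  No sum-to-one constraint is
applied: abundances are in the units of the library normalization and need
not sum to anything.

Fit quality is summarized by the per-pixel RMS error

    RMS_error = sqrt( (1/n) Σ_λ (x_measured − x_fit)² )

with n the number of bands, and by percent RMS error
(100 · RMS error / RMS signal), computed either image-averaged (ratio of
frame means) or pixelwise (per-pixel ratio) — the two behave differently
on heterogeneous frames, e.g. under photobleaching.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import nnls as _scipy_nnls

from .datamodel import SpectralCube, SpectralLibrary
from .library import condition_report

__all__ = ["UnmixResult", "LinearUnmixing", "unmix", "percent_rms_error", "reconstruct"]

_COND_LIMIT = 1e8


@dataclass
class UnmixResult:
    """Abundance maps plus reconstruction diagnostics from one unmixing fit."""

    names: list
    abundances: np.ndarray  # (rows, cols, k)
    fit: SpectralCube
    rms_error: np.ndarray  # (rows, cols)
    rms_signal: np.ndarray  # (rows, cols)
    solver: str

    def abundance(self, name: str) -> np.ndarray:
        """The 2-D abundance image of one endmember."""
        return self.abundances[:, :, self.names.index(name)]

    def abundance_maps(self) -> dict:
        return {n: self.abundance(n) for n in self.names}

    def percent_rms_error(self, mode: str = "image_averaged"):
        return percent_rms_error(self, mode)

    def summary(self) -> str:
        lines = [
            f"Linear unmixing ({self.solver}), {len(self.names)} endmembers, "
            f"{self.rms_error.size} pixels, {self.fit.axis.n_bands} bands",
            f"{'endmember':<12} {'mean abundance':>14} {'max abundance':>14}",
        ]
        for i, name in enumerate(self.names):
            a = self.abundances[:, :, i]
            lines.append(f"{name:<12} {a.mean():>14.4g} {a.max():>14.4g}")
        lines.append(f"image-averaged %RMS error: {percent_rms_error(self):.3f}")
        return "\n".join(lines)


class LinearUnmixing:
    """Least-squares decomposition of a cube onto a spectral library.

    ``LinearUnmixing(cube, library).fit()`` returns an :class:`UnmixResult`
    carrying per-endmember abundance images, the reconstructed cube, and
    per-pixel RMS error / RMS signal images.
    """

    def __init__(self, cube: SpectralCube, library: SpectralLibrary, solver: str = "ols"):
        if not cube.axis.matches(library.axis):
            raise ValueError("cube and library are on different wavelength axes")
        if library.n_endmembers > cube.axis.n_bands:
            raise ValueError(
                f"library has {library.n_endmembers} endmembers but the cube only "
                f"{cube.axis.n_bands} bands; the problem is underdetermined"
            )
        if solver not in ("ols", "nnls"):
            raise ValueError(f"solver must be 'ols' or 'nnls', got {solver!r}")
        cond = np.linalg.cond(library.matrix)
        if not np.isfinite(cond) or cond > _COND_LIMIT:
            report = condition_report(library)
            raise ValueError(
                f"library matrix is rank-deficient or near-singular "
                f"(condition number {cond:.3g}); diagnostics: {report['flags']}"
            )
        self.cube = cube
        self.library = library
        self.solver = solver

    def fit(self) -> UnmixResult:
        S = self.library.matrix  # (bands, k)
        X = self.cube.pixel_spectra()  # (npix, bands)
        if self.solver == "ols":
            coef, *_ = np.linalg.lstsq(S, X.T, rcond=None)  # (k, npix)
            A = coef.T
        else:
            A = np.empty((X.shape[0], S.shape[1]))
            for i, x in enumerate(X):
                A[i], _ = _scipy_nnls(S, x)
        fit_flat = A @ S.T  # (npix, bands)
        n = self.cube.axis.n_bands
        resid = X - fit_flat
        rms_error = np.sqrt((resid ** 2).mean(axis=1))
        rms_signal = np.sqrt((X ** 2).mean(axis=1))
        rows, cols = self.cube.data.shape[:2]
        fit_cube = self.cube.with_data(fit_flat.reshape(rows, cols, n),
                                       reconstruction=True, solver=self.solver)
        return UnmixResult(
            names=list(self.library.names),
            abundances=A.reshape(rows, cols, self.library.n_endmembers),
            fit=fit_cube,
            rms_error=rms_error.reshape(rows, cols),
            rms_signal=rms_signal.reshape(rows, cols),
            solver=self.solver,
        )


def unmix(cube: SpectralCube, library: SpectralLibrary, solver: str = "ols") -> UnmixResult:
    """Functional wrapper: ``LinearUnmixing(cube, library, solver).fit()``."""
    return LinearUnmixing(cube, library, solver).fit()


def percent_rms_error(result: UnmixResult, mode: str = "image_averaged"):
    """Percent RMS unmixing error.

    ``image_averaged``: 100 × mean(RMS error) / mean(RMS signal) over the
    frame, a single scalar.  ``pixelwise``: 100 × RMS error / RMS signal
    per pixel; zero-signal pixels are undefined (NaN) and their count is
    recorded on the returned array's ``excluded`` attribute via a second
    return — the function returns ``(image, n_excluded)`` in this mode.
    """
    if mode == "image_averaged":
        denom = result.rms_signal.mean()
        if denom <= 0:
            raise ValueError("image-averaged RMS signal is zero; percent error undefined")
        return 100.0 * result.rms_error.mean() / denom
    if mode == "pixelwise":
        defined = result.rms_signal > 0
        out = np.full(result.rms_error.shape, np.nan)
        out[defined] = 100.0 * result.rms_error[defined] / result.rms_signal[defined]
        n_excluded = int((~defined).sum())
        return out, n_excluded
    raise ValueError(f"mode must be 'image_averaged' or 'pixelwise', got {mode!r}")


def reconstruct(abundances, library: SpectralLibrary) -> SpectralCube:
    """Mix abundance maps back into a cube (the model's forward direction).

    ``abundances`` is an (rows, cols, k) array ordered like the library, or
    a dict of per-endmember 2-D images keyed by name.
    """
    if isinstance(abundances, dict):
        stack = np.stack([np.asarray(abundances[n], dtype=float) for n in library.names], axis=-1)
    else:
        stack = np.asarray(abundances, dtype=float)
        if stack.shape[-1] != library.n_endmembers:
            raise ValueError(
                f"abundance stack has {stack.shape[-1]} planes, library {library.n_endmembers} endmembers"
            )
    data = stack @ library.spectra
    return SpectralCube(data, library.axis, 16, {"reconstruction": True})
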