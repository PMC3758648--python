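"""Synthetic hyperspectral acquisitions.

Generates three-endmember scenes (a GFP-like fluorophore, a Hoechst-like
nuclear stain, and tissue autofluorescence) over the 462–648 nm emission
range in 6 nm bands, then pushes the noise-free signal through a detector
model emulating either a widefield EMCCD or a confocal PMT system.

The detector model is deliberately abstract.  Photon arrival is Poisson in
the illumination-scaled signal; the multiplicative noise of an EM register
or PMT dynode chain is a variance-inflation factor F on that branch
(variance = F² · gain² · mean); Gaussian read noise and a digitizer offset
follow, then rounding and clipping to the bit depth.  Pinhole diameter,
lamp percentage and laser power are not modelled optically — they all fold
into ``illumination_scale``, which is enough to reproduce the shot-noise
trends (SNR ∝ √photons) the characterization pipeline measures.

Photobleaching is mono-exponential per endmember: abundance maps decay as
exp(−k·t) before mixing and detection.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .datamodel import (
    AcquisitionSeries,
    SpectralCube,
    SpectralLibrary,
    WavelengthAxis,
    make_wavelength_axis,
)

__all__ = [
    "EndmemberModel", "SceneObject", "SceneSpec", "DetectorModel", "SystemPreset",
    "gaussian_endmember", "build_simulated_library", "render_scene",
    "acquire", "simulate_bleaching", "preset", "default_axis", "default_scene",
]

FOUR_LN2 = 4.0 * math.log(2.0)


def default_axis() -> WavelengthAxis:
    """The acquisition grid used throughout: 462–648 nm in 6 nm bands (32)."""
    return make_wavelength_axis(462.0, 648.0, 6.0)


@dataclass(frozen=True)
class EndmemberModel:
    """A single-Gaussian emission spectrum.

    ``width_nm`` is the full width at half maximum; ``relative_brightness``
    scales the peak value.  Real autofluorescence is a mixture of
    endogenous fluorophores, but a single Gaussian captures the one feature
    the characterization needs: where the peak sits.
    """

    name: str
    peak_nm: float
    width_nm: float
    relative_brightness: float = 1.0

    def __post_init__(self):
        if self.width_nm <= 0:
            raise ValueError(f"{self.name}: width_nm must be positive")
        if self.relative_brightness <= 0:
            raise ValueError(f"{self.name}: relative_brightness must be positive")


def gaussian_endmember(model: EndmemberModel, axis: WavelengthAxis) -> np.ndarray:
    """Sample the Gaussian emission profile at the axis band centers.

    value(λ) = brightness · exp(−4 ln2 · (λ − peak)² / FWHM²), so the
    profile equals half the brightness at peak ± FWHM/2.
    """
    lam = axis.centers
    return model.relative_brightness * np.exp(
        -FOUR_LN2 * (lam - model.peak_nm) ** 2 / model.width_nm ** 2
    )


def build_simulated_library(models, axis: WavelengthAxis,
                            normalization: str = "raw") -> SpectralLibrary:
    spectra = np.stack([gaussian_endmember(m, axis) for m in models])
    lib = SpectralLibrary([m.name for m in models], spectra, axis, "raw")
    return lib.normalized(normalization)


@dataclass(frozen=True)
class SceneObject:
    """One geometric primitive carrying an endmember at a given abundance.

    kind: ``background`` fills the frame; ``disk`` and ``annulus`` need a
    center (row, col) and radius / (r_inner, r_outer) in pixels.  A center
    of None is placed randomly by the scene seed.
    """

    endmember: str
    kind: str
    level: float
    center: tuple | None = None
    radius: float | None = None
    r_inner: float | None = None
    r_outer: float | None = None

    def __post_init__(self):
        if self.level < 0:
            raise ValueError(f"abundance level must be >= 0, got {self.level}")
        if self.kind not in ("background", "disk", "annulus"):
            raise ValueError(f"unknown geometry {self.kind!r}")


@dataclass
class SceneSpec:
    shape: tuple
    objects: list
    seed: int = 0


def _object_mask(obj: SceneObject, shape, rng) -> np.ndarray:
    rows, cols = shape
    if obj.kind == "background":
        return np.ones(shape, dtype=bool)
    if obj.center is None:
        center = (rng.uniform(0.25, 0.75) * rows, rng.uniform(0.25, 0.75) * cols)
    else:
        center = obj.center
    rr, cc = np.ogrid[:rows, :cols]
    d2 = (rr - center[0]) ** 2 + (cc - center[1]) ** 2
    if obj.kind == "disk":
        if obj.radius is None:
            raise ValueError("disk object needs a radius")
        return d2 <= obj.radius ** 2
    if obj.r_inner is None or obj.r_outer is None:
        raise ValueError("annulus object needs r_inner and r_outer")
    return (d2 >= obj.r_inner ** 2) & (d2 <= obj.r_outer ** 2)


def render_scene(spec: SceneSpec, library: SpectralLibrary):
    """Ground-truth abundance maps and the noise-free cube they mix to.

    Returns ``(abundances, cube)`` where abundances maps endmember name to
    a 2-D image.  The cube is the per-pixel abundance-weighted sum of the
    library spectra — the exact linear mixing model the unmixing stage
    assumes, so unmixing this cube recovers the abundances.
    """
    rows, cols = spec.shape
    if rows <= 0 or cols <= 0:
        raise ValueError(f"scene shape must be positive, got {spec.shape}")
    rng = np.random.default_rng(spec.seed)
    abundances = {name: np.zeros(spec.shape) for name in library.names}
    for obj in spec.objects:
        if obj.endmember not in library.names:
            raise ValueError(f"scene references unknown endmember {obj.endmember!r}")
        mask = _object_mask(obj, spec.shape, rng)
        abundances[obj.endmember][mask] += obj.level
    stack = np.stack([abundances[n] for n in library.names], axis=-1)  # (r, c, k)
    data = stack @ library.spectra  # (r, c, bands)
    cube = SpectralCube(data, library.axis, 16, {"noise_free": True, "scene_seed": spec.seed})
    return abundances, cube


@dataclass(frozen=True)
class DetectorModel:
    """Abstract detector: photon statistics plus digitization.

    gain — counts per detected photon; excess_noise_factor — multiplicative
    noise of the EM register / dynode chain (F ≥ 1, variance inflated by
    F²); read_noise — Gaussian counts RMS added after amplification;
    offset — digitizer baseline counts; illumination_scale — folds lamp
    percentage, laser power and pinhole transmission into one photon-rate
    multiplier.
    """

    kind: str
    gain: float = 1.0
    read_noise: float = 0.0
    excess_noise_factor: float = 1.0
    offset: float = 0.0
    bit_depth: int = 16
    illumination_scale: float = 1.0

    def __post_init__(self):
        if self.kind not in ("emccd", "pmt"):
            raise ValueError(f"detector kind must be emccd or pmt, got {self.kind!r}")
        if self.gain <= 0:
            raise ValueError("gain must be positive")
        if self.read_noise < 0:
            raise ValueError("read_noise must be >= 0")
        if self.excess_noise_factor < 1:
            raise ValueError("excess_noise_factor must be >= 1")
        if not 8 <= self.bit_depth <= 16:
            raise ValueError("bit_depth must be within 8..16")


def _detect_one(photon_mean: np.ndarray, detector: DetectorModel, rng) -> np.ndarray:
    photons = rng.poisson(photon_mean).astype(float)
    signal = detector.gain * photons
    f2 = detector.excess_noise_factor ** 2
    if f2 > 1:
        # inflate the shot-noise branch to variance F^2 * gain^2 * mean
        extra_sd = detector.gain * np.sqrt((f2 - 1.0) * photon_mean)
        signal = signal + rng.normal(0.0, 1.0, photon_mean.shape) * extra_sd
    if detector.read_noise > 0:
        signal = signal + rng.normal(0.0, detector.read_noise, photon_mean.shape)
    signal = signal + detector.offset
    ceiling = 2 ** detector.bit_depth - 1
    return np.clip(np.rint(signal), 0, ceiling)


def acquire(noise_free: SpectralCube, detector: DetectorModel,
            n_replicates: int = 5, seed: int | None = 0) -> AcquisitionSeries:
    """Simulate sequential replicate acquisitions of a static scene.

    Replicates are i.i.d. given the seed; the same seed reproduces the
    series bit for bit.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    rng = np.random.default_rng(seed)
    lam = detector.illumination_scale * np.clip(noise_free.data, 0, None)
    cubes = []
    for i in range(n_replicates):
        data = _detect_one(lam, detector, rng)
        cubes.append(SpectralCube(
            data, noise_free.axis, detector.bit_depth,
            {"replicate": i, "seed": seed, "detector": detector.kind},
        ))
    return AcquisitionSeries(cubes, "replicate")


def simulate_bleaching(abundances: dict, library: SpectralLibrary, rates: dict,
                       times_s, detector: DetectorModel | None = None,
                       seed: int | None = 0) -> AcquisitionSeries:
    """Continuous-illumination time series with per-endmember decay.

    Each endmember's abundance map is scaled by exp(−rate·t) before mixing;
    ``rates`` maps endmember name to a decay constant in 1/s (missing names
    mean no bleaching).  With ``detector=None`` the series is noise-free,
    which is what closed-form rate-recovery checks use.
    """
    times_s = np.asarray(times_s, dtype=float)
    if len(times_s) and not np.all(np.diff(times_s) > 0):
        raise ValueError("times_s must be strictly increasing")
    for name, k in rates.items():
        if k < 0:
            raise ValueError(f"decay rate for {name!r} must be >= 0")
    rng = np.random.default_rng(seed)
    cubes = []
    for t in times_s:
        stack = np.stack(
            [abundances[n] * math.exp(-rates.get(n, 0.0) * t) for n in library.names],
            axis=-1,
        )
        data = stack @ library.spectra
        if detector is None:
            cube = SpectralCube(data, library.axis, 16, {"noise_free": True, "time_s": t})
        else:
            lam = detector.illumination_scale * np.clip(data, 0, None)
            cube = SpectralCube(
                _detect_one(lam, detector, rng), library.axis, detector.bit_depth,
                {"time_s": t, "seed": seed, "detector": detector.kind},
            )
        cubes.append(cube)
    return AcquisitionSeries(cubes, "timeseries", times_s)


@dataclass(frozen=True)
class SystemPreset:
    """A named microscope emulation: detector model plus endmember triple."""

    system: str
    detector: DetectorModel
    endmembers: tuple

    @property
    def af_peak(self) -> float:
        for m in self.endmembers:
            if m.name == "AF":
                return m.peak_nm
        raise KeyError("preset has no AF endmember")

    def library(self, axis: WavelengthAxis | None = None,
                normalization: str = "peak1") -> SpectralLibrary:
        return build_simulated_library(self.endmembers, axis or default_axis(), normalization)


# GFP and Hoechst emission are instrument-independent; the bulk
# autofluorescence peak shifts with the excitation used (505 nm under the
# widefield's 430/24 filter, 545 nm under the confocal's 458 nm laser).
_GFP = EndmemberModel("GFP", peak_nm=510.0, width_nm=40.0, relative_brightness=1.0)
_HOECHST = EndmemberModel("Hoechst", peak_nm=461.0, width_nm=60.0, relative_brightness=0.8)

# Detector constants place typical simulated signals in the raw-SNR regimes
# the two system classes occupy (roughly 5-30 for the confocal PMT, 1.5-5
# for the widefield EMCCD with its higher background and excess noise).
_PRESETS = {
    "widefield": SystemPreset(
        "widefield",
        DetectorModel(kind="emccd", gain=20.0, read_noise=15.0,
                      excess_noise_factor=2.0, offset=100.0, bit_depth=16,
                      illumination_scale=0.5),
        (_GFP, _HOECHST, EndmemberModel("AF", peak_nm=505.0, width_nm=90.0,
                                        relative_brightness=0.6)),
    ),
    "confocal": SystemPreset(
        "confocal",
        DetectorModel(kind="pmt", gain=4.0, read_noise=2.0,
                      excess_noise_factor=1.3, offset=10.0, bit_depth=12,
                      illumination_scale=1.0),
        (_GFP, _HOECHST, EndmemberModel("AF", peak_nm=545.0, width_nm=90.0,
                                        relative_brightness=0.6)),
    ),
}


def preset(system: str) -> SystemPreset:
    """Widefield-EMCCD or confocal-PMT emulation preset."""
    try:
        return _PRESETS[system]
    except KeyError:
        raise ValueError(
            f"unknown system {system!r}; available: {sorted(_PRESETS)}"
        ) from None


def default_scene(shape=(64, 64), seed: int = 0,
                  af_level: float = 150.0, gfp_level: float = 400.0,
                  hoechst_level: float = 300.0) -> SceneSpec:
    """The stock test field of view: autofluorescent background everywhere,
    a GFP-positive cell body (disk) and a Hoechst-stained nucleus (disk).

    Abundance levels are expected photon counts per band-peak at unit
    illumination — a few hundred photons, typical of fixed-tissue
    fluorescence at moderate exposure.
    """
    rows, cols = shape
    return SceneSpec(
        shape=tuple(shape),
        objects=[
            SceneObject("AF", "background", af_level),
            SceneObject("GFP", "disk", gfp_level,
                        center=(rows * 0.38, cols * 0.38), radius=min(rows, cols) * 0.22),
            SceneObject("Hoechst", "disk", hoechst_level,
                        center=(rows * 0.65, cols * 0.62), radius=min(rows, cols) * 0.14),
        ],
        seed=seed,
    )
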