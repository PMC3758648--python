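# Methods

This note records the models `hypercal` implements, the conventions and
numerical choices behind them, and what the bundled simulator does and does
not emulate.

## Data model and conventions

Images are row-major with pixel (0, 0) at the top-left and 0-based
indices; band index 0 is the shortest wavelength. The wavelength axis is a
uniform grid of band *centers* with inclusive endpoints — a 462–648 nm
range at a 6 nm increment is exactly 32 bands; bandwidth, when known, is
metadata and never enters a computation. Raw cubes carry a detector bit
depth and live in [0, 2^bits − 1]; corrected cubes may exceed that ceiling
but are clamped at 0 (negative residuals after dark subtraction are noise;
the clamp count is recorded in provenance).

Replicate statistics use the sample standard deviation (n − 1
denominator) throughout — with five replicates, the typical case, the
choice is material, so it is fixed and documented here. A pixel/band where
σ = 0 has no defined SNR; it is masked and excluded from averages rather
than mapped to infinity. "σ = 0" is applied with a relative tolerance
(σ ≤ |μ|·1e−12) because identical replicates stored as floats can leave a
residual σ of order μ·ε from accumulation rounding, which is still "no
variation".

## Flat spectral correction

The transfer function TF(λ) = (I_bright − I_dark)/I_lamp is computed from
dark/bright calibration cubes reduced by spatial averaging over the full
frame (a per-pixel reduction is available for spatially non-uniform
response), with the certified lamp spectrum linearly interpolated onto the
acquisition axis (never extrapolated). The correction coefficient is
CC = 1/TF and corrected intensities are
I_corr(λ) = max(0, I_raw(λ) − I_dark(λ)) · CC(λ). Bands where TF ≤ 0 abort
the correction and are named in the error — interpolating over them would
silently fabricate instrument response. Confocal-class systems with
calibrated detectors skip the flat correction; plain background
subtraction (a per-band spectrum, or the pixel-averaged spectrum of a
blank ROI) is still applied.

Two identities pin the implementation: correcting the bright cube itself
returns the lamp spectrum at every pixel, and multiplying a corrected cube
by TF and adding back the dark spectrum recovers the raw cube wherever no
clamping occurred.

## Endmember libraries

An endmember spectrum is extracted from a background-subtracted
single-fluorophore control as the pixel-averaged spectrum over an ROI of
bright pixels. The ROI is defined by a quantile threshold on the
total-emission image (default 0.95): a quantile is reproducible across
exposure scales where an absolute count threshold is not; Otsu's method is
available as an alternative. Extraction is scale-equivariant, and raising
the quantile never grows the ROI.

Libraries are stored raw and normalized on demand. Unmixing defaults to
peak-normalized spectra (`peak1`), so abundances come out in
peak-intensity units — the same units the spike-in study uses for its
added-signal levels, which is what makes its ideal response slope exactly 1.
A conditioning report (pairwise cosine similarities, matrix condition
number) flags near-collinear endmembers before they poison the
least-squares problem.

## Linear unmixing and error metrics

Per pixel, the abundance vector minimizes Σ_λ (x_meas − Σ_k a_k s_k(λ))².
The default solver is unconstrained OLS, matching the common behaviour of
ENVI-style unmixing tools; NNLS (a ≥ 0) is available because negative
abundances are non-physical. No sum-to-one constraint is applied —
abundances are free-scale coefficients. A library with more endmembers
than bands is rejected as underdetermined (equality — an exactly
determined system — is allowed); a condition number above 1e8 is rejected
as rank-deficient with the conditioning report attached.

RMS error per pixel is √((1/n) Σ_λ (x_meas − x_fit)²) with n the number of
bands (32 on the standard axis). Percent RMS error is reported in two
modes that diverge on heterogeneous frames: image-averaged
(100 · mean(RMS error)/mean(RMS signal), a brightness-weighted scalar) and
pixelwise (the per-pixel ratio; zero-signal pixels are excluded with a
count). Both are tracked over bleaching time series because they trend
differently as signal drains.

For cross-system comparisons, cubes from detectors of different bit depths
are linearly rescaled to a common depth by (2^target − 1)/(2^source − 1),
mapping 0 → 0 and full scale → full scale exactly.

## SNR, CV and irradiance

SNR = μ/σ across sequential replicates, per pixel per band. The composite
SNR averages defined values over the frame (ROI-restricted first when an
ROI is given, then averaged) and over all wavelengths; per-band SNR
averages within each band. Unmixed SNR unmixes each replicate
independently and applies the same μ/σ statistics to the abundance images
— unmixing pools information across bands, so unmixed SNR typically
exceeds raw-band SNR. The CV of a fluorophore is the sample SD over mean
of its ROI-mean total emission across replicates. Excitation irradiance is
integrated over a wavelength window (filter band ± 40 nm, or a 10 nm
window around a laser line) by the trapezoidal rule with interpolated
window endpoints, and rejects windows outside the table's support.

## Photobleaching analysis

Kinetics are mono-exponential per endmember — the minimal model that
supports differential photobleaching and rate recovery; bi-exponential
photophysics is out of scope. Curves are built by unmixing each time
point, averaging each endmember's abundance over the whole field of view
(ROI-restricted curves are an option), and normalizing to the first time
point, so every curve starts at exactly 1. An optional subsampling
interval analyzes a coarser time grid than was acquired (e.g. 5-minute
analysis of a 30-second cadence).

The rate fit is weighted least squares on ln I = −k t with no intercept
(the curve is 1 at t = 0 by construction) and weights proportional to
intensity, which stops late near-zero points — whose log values explode —
from dominating. Non-positive intensities are excluded and counted. A
constant curve fits k = 0 exactly, and exact exponential samples invert to
the generating rate to machine precision.

## Spike-in sensitivity study

The target spectrum, scaled so its maximum band equals the requested peak
intensity (area-anchored scaling is an option), is added to every pixel of
a 30 × 30 pixel square ROI (900 pixels) of a control cube containing no
target signal; default levels run 0–1000 A.U. in steps of 100. Each spiked
cube is unmixed and the target-abundance distribution in the ROI recorded.
The response line is an unconstrained OLS fit of mean ROI abundance
against level (the intercept is reported, not forced to zero).

The detection threshold is a quantile of the level-0 ROI abundance
distribution, estimated by nearest rank — the smallest sample value whose
cumulative fraction reaches q — which is distribution-free and exact on
small samples (on 900 values at q = 0.985 that is rank ⌈886.5⌉ = 887).
The default quantile is 0.985, with any other value (e.g. 0.9985)
available as a parameter. A pixel is *detected* when its abundance
strictly exceeds the threshold: the threshold is by construction the
largest null-sample value still classed negative, which keeps the level-0
in-ROI detection count at or below ⌈(1 − q) · 900⌉ and makes the
noise-free study report exactly zero false positives. The standalone
`classify_positives` helper defaults to an inclusive ≥ comparison (useful
when the threshold is chosen independently of the sample); the strict mode
it also offers is what the study driver uses. False positives are
positives outside the spiked ROI, with the whole-image pixel count as
denominator.

## The simulator

Scenes are built from geometric primitives (background, disks, annuli)
carrying endmember abundances; the noise-free cube is the per-pixel
abundance-weighted sum of library spectra — exactly the linear mixing
model the unmixing stage assumes, so noise-free recovery is exact by
construction and any deviation measures solver error.

Endmember spectra are single Gaussians
b · exp(−4 ln 2 (λ − peak)²/FWHM²): GFP peaks at 510 nm (FWHM 40 nm),
Hoechst at 461 nm (FWHM 60 nm) in both presets; bulk autofluorescence
peaks at 505 nm under the widefield preset and 545 nm under the confocal
preset, reflecting the different excitation each system class uses. Real
autofluorescence is a multi-fluorophore mixture; only the peak position
matters to what the toolkit tests.

Detection is, per replicate: photons ~ Poisson(illumination_scale ×
signal), amplified by the gain, with the multiplicative noise of an EM
register or PMT dynode chain modelled as a variance-inflation factor F on
the shot-noise branch (variance = F²·g²·mean) — one mechanism for both
detector kinds keeps the presets comparable — then Gaussian read noise, a
digitizer offset, rounding, and clipping to the bit depth. Replicates are
i.i.d. given the seed and bit-identical on reruns. Pinhole diameter, lamp
percentage and laser power are not modelled optically; they fold into
`illumination_scale`, which is sufficient to reproduce the √photons SNR
trends the characterization measures.

Preset constants (widefield EMCCD: gain 20, read noise 15, F = 2.0,
offset 100, 16-bit, illumination 0.5; confocal PMT: gain 4, read noise 2,
F = 1.3, offset 10, 12-bit, illumination 1.0) were chosen once so that
typical simulated scenes (tens to hundreds of expected photons per band)
land in the raw-SNR regimes the two system classes occupy — roughly 1.5–5
for the widefield class and 5–30 for the confocal class — and are plain
dataclass fields for anyone who wants other regimes.

What the simulator does **not** emulate: optical point-spread functions
and 3-D sectioning, raster-scan dwell-time effects, tunable-filter
spectral crosstalk, spatially structured background, and multi-component
autofluorescence. Passing tests therefore demonstrate the correctness of
the analysis chain under the linear-mixing, shot-noise model — not the
performance of any physical instrument. Instrument-specific headline
numbers (absolute SNR ranges, %RMS levels, false-positive percentages)
depend on real hardware and real tissue and are reproduced only
directionally here.

## Problem sizes and determinism

The default test and characterization scenes are 32–64 pixel square frames
with 32 bands, 5 replicates for SNR, 500 replicates for the Poisson
√N check, 11 spike-in levels, 11 bleaching time points and 20 seeded runs
for the rate-ordering check — sizes at which every statistical assertion
is comfortably inside its tolerance while the whole suite runs in seconds.
All randomness flows from explicit integer seeds (`numpy.random.default_rng`);
identical inputs and seed reproduce every output bit for bit.

## Known limitations

* Mono-exponential bleaching only; fluorophores with strong reversible
  dark-state kinetics will not fit well.
* The flat correction assumes a spatially uniform spectral response unless
  the per-pixel calibration variant is used; no spatially-dependent
  background model beyond that.
* OLS abundances can be negative on noisy pixels; NNLS removes the
  artifact at ~100× the per-pixel cost.
* The nearest-rank threshold is a step function of the null sample; with
  900 null pixels the achievable specificity levels are quantized in steps
  of 1/900.
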