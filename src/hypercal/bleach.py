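"""Photobleaching time-series analysis.

Continuous illumination bleaches each fluorophore at its own rate; in a
multi-fluorophore assay this differential photobleaching distorts
quantification over time.  The analysis unmixes each time point, averages
each endmember's abundance over the field of view, normalizes to the
initial value, and fits a mono-exponential decay I(t) = exp(−k·t) to
recover the per-endmember rate constant k (1/s).

The fit is weighted log-linear through the origin: with the curve
normalized to 1 at t = 0, ln I = −k·t, and weights proportional to the
intensity keep the late, noisy, near-zero points from dominating the log
fit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datamodel import AcquisitionSeries, SpectralLibrary, validate_series
from .unmix import percent_rms_error, unmix

__all__ = ["bleaching_curves", "DecayFit", "fit_decay_rate", "error_vs_time"]


def _require_timeseries(series: AcquisitionSeries, min_points: int = 3) -> None:
    problems = validate_series(series)
    if problems:
        raise ValueError(f"invalid series: {problems}")
    if series.kind != "timeseries":
        raise ValueError(f"timeseries required, got kind={series.kind!r}")
    if len(series.cubes) < min_points:
        raise ValueError(f"need >= {min_points} time points, got {len(series.cubes)}")


def _subsample(series: AcquisitionSeries, interval_s: float) -> AcquisitionSeries:
    """Keep time points on a regular grid from t0 (e.g. analyze 5-minute
    intervals out of a 30-second acquisition cadence)."""
    t0 = series.times_s[0]
    keep = [i for i, t in enumerate(series.times_s)
            if abs((t - t0) % interval_s) < 1e-9 or abs((t - t0) % interval_s - interval_s) < 1e-9]
    return AcquisitionSeries([series.cubes[i] for i in keep], "timeseries",
                             series.times_s[keep])


def bleaching_curves(series: AcquisitionSeries, library: SpectralLibrary,
                     solver: str = "ols", subsample_s: float | None = None) -> pd.DataFrame:
    """Normalized per-endmember decay curves.

    Each time point is unmixed; each endmember's abundance is averaged over
    the entire field of view and divided by its value at the first time
    point, so every curve starts at exactly 1.  Endmembers whose initial
    abundance is ≤ 0 cannot be normalized; they are left as raw means and
    listed in the result's ``attrs["not_normalized"]``.

    Returns a DataFrame with a ``time_s`` column and one column per
    endmember.
    """
    _require_timeseries(series)
    if subsample_s is not None:
        series = _subsample(series, subsample_s)
        _require_timeseries(series)
    means = []
    for cube in series.cubes:
        res = unmix(cube, library, solver)
        means.append([res.abundance(n).mean() for n in library.names])
    means = np.asarray(means)  # (n_times, k)
    df = pd.DataFrame({"time_s": series.times_s})
    flagged = []
    for j, name in enumerate(library.names):
        initial = means[0, j]
        if initial <= 0:
            flagged.append(name)
            df[name] = means[:, j]
        else:
            df[name] = means[:, j] / initial
    df.attrs["not_normalized"] = flagged
    return df


@dataclass
class DecayFit:
    """Mono-exponential decay fit I(t) = exp(−rate·t)."""

    rate: float  # 1/s
    residual_rms: float  # RMS of log-space residuals
    n_used: int
    n_excluded: int  # non-positive intensities dropped from the log fit

    def half_life(self) -> float:
        return np.inf if self.rate == 0 else np.log(2) / self.rate


def fit_decay_rate(times_s, intensities) -> DecayFit:
    """Fit a normalized decay curve, returning the rate constant.

    Weighted least squares on ln I = −k·t (no intercept: the curve is
    normalized to 1 at its first point) with weights ∝ intensity.
    Non-positive intensities are excluded and counted.
    """
    t = np.asarray(times_s, dtype=float)
    y = np.asarray(intensities, dtype=float)
    if len(t) != len(y):
        raise ValueError("times and intensities must have equal length")
    if len(t) < 3:
        raise ValueError(f"need >= 3 points to fit a decay, got {len(t)}")
    pos = y > 0
    n_excluded = int((~pos).sum())
    t, y = t[pos], y[pos]
    if len(t) < 2:
        raise ValueError("fewer than 2 positive intensities; decay fit impossible")
    w = y
    denom = float((w * t * t).sum())
    if denom == 0:  # all mass at t = 0; no decay information
        return DecayFit(0.0, 0.0, len(t), n_excluded)
    logy = np.log(y)
    k = -float((w * t * logy).sum()) / denom
    resid = logy + k * t
    return DecayFit(k, float(np.sqrt(np.mean(resid ** 2))), len(t), n_excluded)


def error_vs_time(series: AcquisitionSeries, library: SpectralLibrary,
                  solver: str = "ols", subsample_s: float | None = None) -> pd.DataFrame:
    """Percent RMS unmixing error at each time point, in both modes.

    Returns a DataFrame with columns ``time_s``,
    ``pct_rms_image_averaged`` (ratio of frame-mean RMS error to
    frame-mean RMS signal) and ``pct_rms_pixelwise_mean`` (mean of the
    per-pixel ratios) — the two diverge as bleaching makes the frame
    heterogeneous.
    """
    _require_timeseries(series)
    if subsample_s is not None:
        series = _subsample(series, subsample_s)
        _require_timeseries(series)
    rows = []
    for t, cube in zip(series.times_s, series.cubes):
        res = unmix(cube, library, solver)
        img_avg = percent_rms_error(res, "image_averaged")
        pixelwise, _ = percent_rms_error(res, "pixelwise")
        rows.append((t, img_avg, float(np.nanmean(pixelwise))))
    return pd.DataFrame(rows, columns=["time_s", "pct_rms_image_averaged",
                                       "pct_rms_pixelwise_mean"])


def plot_bleaching_curves(curves: pd.DataFrame, ax=None):
    """Plot normalized decay curves (one line per endmember)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for col in curves.columns:
        if col == "time_s":
            continue
        ax.plot(curves["time_s"], curves[col], marker="o", label=col)
    ax.set_xlabel("time (s)")
    ax.set_ylabel("normalized unmixed intensity")
    ax.set_ylim(bottom=0)
    ax.legend()
    return ax
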