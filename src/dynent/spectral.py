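"""Spectral signature β of a voltage series.

β is the negated slope of the power spectral density on log10–log10 axes:
β ≈ 1 marks 1/f ("pink") fluctuations, β = 0 white noise and β = 2 Brownian
motion.  The PSD is a segment-averaged tapered (Welch) periodogram; the
regression band excludes the lowest bins, which detrending distorts, and the
top octave, where the taper rolls off.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .signal_io import VoltageSeries

__all__ = ["SpectralFit", "power_spectrum", "spectral_signature"]

#: Number of lowest nonzero frequency bins excluded from the default fit band.
N_LOW_BINS_EXCLUDED = 3


def _as_series(x) -> VoltageSeries:
    if isinstance(x, VoltageSeries):
        return x
    return VoltageSeries(np.asarray(x, dtype=float), 1.0)


@dataclass(frozen=True)
class SpectralFit:
    """Result of the log–log PSD slope regression."""

    beta: float
    intercept: float
    fit_freq_range: tuple[float, float]
    n_freqs_used: int
    stderr_beta: float

    def __post_init__(self) -> None:
        lo, hi = self.fit_freq_range
        if not (0 < lo <= hi):
            raise ValueError("fit_freq_range must lie within (0, Nyquist]")
        if self.n_freqs_used < 8:
            raise ValueError("spectral fit needs at least 8 frequency bins")


def power_spectrum(
    series: VoltageSeries | np.ndarray, n_segments: int = 8
) -> tuple[np.ndarray, np.ndarray]:
    """One-sided segment-averaged power spectral density.

    Segments overlap by 50% and carry a Hann taper when ``n_segments > 1``;
    a single segment reduces to the plain (boxcar) periodogram.  The zero
    frequency is dropped, so frequencies lie in (0, Nyquist] and
    ``sum(P) * df`` approximates the series variance (one-sided convention).
    """
    series = _as_series(series)
    x = series.samples
    if x.size < 64:
        raise ValueError(f"power_spectrum needs at least 64 samples, got {x.size}")
    if n_segments < 1:
        raise ValueError("n_segments must be >= 1")
    if n_segments == 1:
        nperseg, window = x.size, "boxcar"
    else:
        nperseg = int(2 * x.size / (n_segments + 1))
        window = "hann"
    freqs, power = sps.welch(
        x,
        fs=series.sampling_rate,
        window=window,
        nperseg=nperseg,
        noverlap=nperseg // 2,
        detrend="constant",
    )
    return freqs[1:], power[1:]


def spectral_signature(
    series: VoltageSeries | np.ndarray,
    fit_freq_range: tuple[float, float] | None = None,
    n_segments: int = 8,
) -> SpectralFit:
    """Estimate β = −slope of log10 PSD vs log10 frequency.

    Parameters
    ----------
    series : VoltageSeries or array
        Input signal (arrays are wrapped at 1 Hz; β is rate-invariant).
    fit_freq_range : (low, high), optional
        Frequency band for the regression.  The default drops the 3 lowest
        nonzero bins and the top octave (Nyquist/2 .. Nyquist).
    n_segments : int
        Welch segment count (50% overlap).

    Returns
    -------
    SpectralFit
        With ``beta`` positive for 1/f-like decay and the OLS standard error.
    """
    series = _as_series(series)
    if len(series) < 256:
        raise ValueError(f"spectral_signature needs at least 256 samples, got {len(series)}")
    freqs, power = power_spectrum(series, n_segments=n_segments)
    if fit_freq_range is None:
        nyquist = series.sampling_rate / 2.0
        lo = freqs[N_LOW_BINS_EXCLUDED]
        hi = nyquist / 2.0
        fit_freq_range = (float(lo), float(hi))
    lo, hi = fit_freq_range
    mask = (freqs >= lo) & (freqs <= hi) & (power > 0)
    n_used = int(mask.sum())
    if n_used < 8:
        raise ValueError(
            f"only {n_used} frequency bins in [{lo:g}, {hi:g}] Hz; need >= 8"
        )
    logf = np.log10(freqs[mask])
    logp = np.log10(power[mask])
    (slope, intercept), cov = np.polyfit(logf, logp, 1, cov=True)
    return SpectralFit(
        beta=float(-slope),
        intercept=float(intercept),
        fit_freq_range=(float(lo), float(hi)),
        n_freqs_used=n_used,
        stderr_beta=float(np.sqrt(cov[0, 0])),
    )
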