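"""Reading, writing and detrending of voltage time series.

A recording is a uniformly sampled scalar voltage signal (μV) acquired at a
known sampling rate, optionally tagged with the bath temperature (°C) at which
it was taken and a replicate index.  Files are two-column delimited text
(``time_s``, ``voltage_uV``); a sweep manifest maps series files to
temperatures and replicates.

Detrending precedes every dynamic-measure computation.  Three variants are
supported: removal of the mean, of a single least-squares line, or of a
contiguous piecewise-linear trend fitted in fixed-length windows.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "VoltageSeries",
    "DetrendSpec",
    "read_series",
    "write_series",
    "read_manifest",
    "write_manifest",
    "detrend",
]

#: Allowed relative jitter of the sampling step before a file is rejected.
JITTER_TOLERANCE = 0.01

_DETREND_MODES = ("mean", "linear", "piecewise_linear")


@dataclass(frozen=True)
class VoltageSeries:
    """One uniformly sampled voltage recording.

    Parameters
    ----------
    samples : ndarray
        Voltage values in μV.
    sampling_rate : float
        Samples per second (Hz); must be positive.
    temperature : float or None
        Bath temperature in °C, if known.
    replicate_id : int
        Replicate channel index within a temperature point.
    label : str
        Free-text identifier (defaults to empty).
    """

    samples: np.ndarray
    sampling_rate: float
    temperature: float | None = None
    replicate_id: int = 0
    label: str = ""

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        if samples.ndim != 1 or samples.size < 2:
            raise ValueError("a voltage series needs at least 2 samples")
        if not np.all(np.isfinite(samples)):
            raise ValueError("voltage series contains NaN or infinite values")
        if not (self.sampling_rate > 0):
            raise ValueError("sampling_rate must be positive")
        object.__setattr__(self, "samples", samples)

    def __len__(self) -> int:
        return self.samples.size

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds, starting at 0."""
        return np.arange(self.samples.size) / self.sampling_rate

    @property
    def duration(self) -> float:
        """Record length in seconds (N / fs)."""
        return self.samples.size / self.sampling_rate

    def with_samples(self, samples: np.ndarray) -> "VoltageSeries":
        """Copy of this series with new sample values, metadata unchanged."""
        return replace(self, samples=np.asarray(samples, dtype=float))


@dataclass(frozen=True)
class DetrendSpec:
    """Detrending prescription.

    ``mode`` is one of ``mean`` (subtract the mean), ``linear`` (remove one
    least-squares line) or ``piecewise_linear`` (remove a separate
    least-squares line per contiguous window of ``window_length`` samples).
    """

    mode: str = "linear"
    window_length: int = 500

    def __post_init__(self) -> None:
        if self.mode not in _DETREND_MODES:
            raise ValueError(
                f"unknown detrend mode {self.mode!r}; expected one of {_DETREND_MODES}"
            )
        if self.mode == "piecewise_linear" and self.window_length < 4:
            raise ValueError("piecewise_linear needs window_length >= 4")


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------


def _sniff_delimiter(first_line: str) -> str:
    return "\t" if first_line.count("\t") >= first_line.count(",") else ","


def _load_two_columns(path: os.PathLike | str) -> tuple[np.ndarray, np.ndarray]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    text = path.read_text()
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise ValueError(f"{path}: empty file")
    sep = _sniff_delimiter(lines[0])
    # tolerate a single header line of non-numeric tokens
    skip = 0
    try:
        [float(tok) for tok in lines[0].split(sep)[:2]]
    except ValueError:
        skip = 1
    try:
        frame = pd.read_csv(
            io.StringIO("\n".join(lines[skip:])), sep=sep, header=None, dtype=float
        )
    except ValueError as exc:
        raise ValueError(f"{path}: non-numeric data row ({exc})") from exc
    if frame.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns (time_s, voltage_uV)")
    t = frame.iloc[:, 0].to_numpy(dtype=float)
    v = frame.iloc[:, 1].to_numpy(dtype=float)
    if np.isnan(t).any() or np.isnan(v).any():
        raise ValueError(f"{path}: missing values in time or voltage column")
    return t, v


def _infer_rate(t: np.ndarray, path: os.PathLike | str) -> float:
    steps = np.diff(t)
    if steps.size == 0 or np.any(steps <= 0):
        raise ValueError(f"{path}: time column must be strictly increasing")
    median = float(np.median(steps))
    jitter = np.max(np.abs(steps - median))
    if jitter > JITTER_TOLERANCE * median:
        raise ValueError(
            f"{path}: non-uniform sampling (max step deviation "
            f"{jitter:.3g} s exceeds {JITTER_TOLERANCE:.0%} of the median step "
            f"{median:.3g} s)"
        )
    return 1.0 / median


def read_series(
    path: os.PathLike | str,
    manifest: os.PathLike | str | None = None,
) -> list[VoltageSeries]:
    """Load voltage recordings from disk.

    With ``manifest=None``, ``path`` names a single two-column series file and
    a one-element list is returned.  With a manifest, ``path`` is the
    directory against which the manifest's ``series_path`` entries are
    resolved, and every listed series is loaded with its temperature and
    replicate attached.

    The sampling rate is inferred from the median time step; files whose step
    jitter exceeds 1% of the median are rejected.
    """
    if manifest is None:
        t, v = _load_two_columns(path)
        rate = _infer_rate(t, path)
        return [VoltageSeries(v, rate, label=Path(path).stem)]

    entries = read_manifest(manifest)
    base = Path(path)
    out = []
    for row in entries.itertuples(index=False):
        fpath = base / row.series_path
        t, v = _load_two_columns(fpath)
        rate = _infer_rate(t, fpath)
        out.append(
            VoltageSeries(
                v,
                rate,
                temperature=float(row.temperature_C),
                replicate_id=int(row.replicate_id),
                label=Path(row.series_path).stem,
            )
        )
    return out


def write_series(series: VoltageSeries, path: os.PathLike | str) -> None:
    """Write a series as delimited text with a ``time_s,voltage_uV`` header."""
    t = series.times
    with open(path, "w") as fh:
        fh.write("time_s,voltage_uV\n")
        for ti, vi in zip(t, series.samples):
            fh.write(f"{ti:.12g},{vi:.17g}\n")


def read_manifest(path: os.PathLike | str) -> pd.DataFrame:
    """Read a sweep manifest (columns series_path, temperature_C, replicate_id)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    first = path.read_text().splitlines()
    if not first:
        raise ValueError(f"{path}: empty manifest")
    sep = _sniff_delimiter(first[0])
    frame = pd.read_csv(path, sep=sep)
    required = {"series_path", "temperature_C", "replicate_id"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"{path}: manifest missing columns {sorted(missing)}")
    if len(frame) == 0:
        raise ValueError(f"{path}: manifest lists no series")
    return frame


def write_manifest(entries: pd.DataFrame | Iterable[dict], path: os.PathLike | str) -> None:
    frame = pd.DataFrame(entries)
    frame.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# detrending
# ---------------------------------------------------------------------------


def _fit_line(idx: np.ndarray, values: np.ndarray) -> np.ndarray:
    slope, intercept = np.polyfit(idx, values, 1)
    return slope * idx + intercept


def detrend(series: VoltageSeries, spec: DetrendSpec | None = None) -> VoltageSeries:
    """Remove the mean, a linear trend, or a piecewise-linear trend.

    Piecewise mode fits one least-squares line per contiguous non-overlapping
    window of ``spec.window_length`` samples; a trailing partial window is
    covered by extrapolating the final full window's fit.  Length and
    sampling rate are never changed, and the operation is idempotent per mode.
    """
    spec = spec or DetrendSpec()
    x = series.samples
    n = x.size
    if spec.mode == "mean":
        return series.with_samples(x - x.mean())
    idx = np.arange(n, dtype=float)
    if spec.mode == "linear":
        return series.with_samples(x - _fit_line(idx, x))
    # piecewise_linear
    w = spec.window_length
    if n < 2 * w:
        raise ValueError(
            f"piecewise_linear detrend needs at least {2 * w} samples "
            f"(2 x window_length), got {n}"
        )
    n_full = n // w
    trend = np.empty(n)
    for k in range(n_full):
        sl = slice(k * w, (k + 1) * w)
        coeff = np.polyfit(idx[sl], x[sl], 1)
        trend[sl] = np.polyval(coeff, idx[sl])
    if n_full * w < n:  # extend last full window's line over the remainder
        trend[n_full * w :] = np.polyval(coeff, idx[n_full * w :])
    return series.with_samples(x - trend)
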