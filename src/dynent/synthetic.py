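"""Synthetic voltage sweeps with known ground truth.

The original recordings are not public, so every pipeline stage is exercised
on simulated sweeps that reproduce their statistical structure: 15
temperature points, two replicate channels of 5000 samples at 4.1 Hz, colored
(1/f^β) noise whose spectral exponent follows an exactly Lorentzian
temperature profile peaking at the physiological temperature, plus white
sensor noise at the ~0.1 μV instrument resolution.  The entropy minimum at
the critical temperature is induced *indirectly*: raising β makes the series
smoother and more regular, which lowers sample/approximate entropy — the
1/f mechanism the analysis is meant to detect, not an imposed entropy value.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .signal_io import VoltageSeries, write_manifest, write_series

__all__ = ["Oscillation", "SweepConfig", "GroundTruth", "colored_noise",
           "generate_sweep", "write_sweep"]

_MAX_SEED = 2**31 - 1


@dataclass(frozen=True)
class Oscillation:
    """Optional damped sinusoidal component added to each series."""

    frequency: float  # Hz
    amplitude: float  # μV
    damping: float = 0.0  # 1/s decay rate


@dataclass(frozen=True)
class SweepConfig:
    """Full generative specification of a synthetic temperature sweep.

    Defaults emulate the study design: 15 temperatures spanning 30–43 °C,
    2 replicates × 5000 samples at 4.1 Hz, spectral exponent rising from the
    saline-control baseline 0.475 to 1.0 on a Lorentzian profile centred at
    36.6 °C with HWHM 2.67 °C, unit-SD signal and 0.1 μV sensor noise.
    """

    temperatures: tuple = tuple(np.linspace(30.0, 43.0, 15))
    n_samples: int = 5000
    sampling_rate: float = 4.1
    n_replicates: int = 2
    beta_baseline: float = 0.475
    beta_peak: float = 1.0
    t_c_true: float = 36.6
    half_width_true: float = 2.67
    signal_sd: float = 1.0
    sensor_noise_sd: float = 0.1
    oscillation: Oscillation | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.beta_peak >= self.beta_baseline >= 0):
            raise ValueError("need beta_peak >= beta_baseline >= 0")
        if self.half_width_true <= 0:
            raise ValueError("half_width_true must be positive")
        if min(self.signal_sd, self.sensor_noise_sd) < 0:
            raise ValueError("standard deviations must be >= 0")
        if self.n_samples < 64 or self.n_replicates < 1:
            raise ValueError("need n_samples >= 64 and n_replicates >= 1")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")

    def beta_profile(self, temperatures=None) -> np.ndarray:
        """Ground-truth β(T): exactly Lorentzian by construction."""
        t = np.asarray(self.temperatures if temperatures is None else temperatures,
                       dtype=float)
        gamma = self.half_width_true
        return self.beta_baseline + (self.beta_peak - self.beta_baseline) * (
            gamma**2 / ((t - self.t_c_true) ** 2 + gamma**2)
        )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["temperatures"] = [float(t) for t in self.temperatures]
        return d


@dataclass(frozen=True)
class GroundTruth:
    """Per-series generative truth (β, seed) plus the generating config."""

    config: SweepConfig
    per_series: pd.DataFrame  # label, temperature, replicate_id, beta_true, seed

    def to_json(self, path) -> None:
        payload = {
            "config": self.config.to_dict(),
            "per_series": self.per_series.to_dict(orient="records"),
        }
        Path(path).write_text(json.dumps(payload, indent=1))


def colored_noise(n: int, beta: float, seed) -> np.ndarray:
    """Unit-SD Gaussian noise with power spectrum ∝ f^(−β).

    Spectral synthesis: independent complex-Gaussian Fourier coefficients
    are scaled by f^(−β/2) and inverse-transformed; the zero-frequency
    coefficient is dropped and the result normalised to zero mean and unit
    (population) SD.  Bit-reproducible for a given integer seed.
    """
    if n < 64:
        raise ValueError("colored_noise needs n >= 64")
    if not (0 <= beta <= 3):
        raise ValueError(f"beta must lie in [0, 3], got {beta}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    freqs = np.fft.rfftfreq(n)
    n_coef = freqs.size
    coef = rng.standard_normal(n_coef) + 1j * rng.standard_normal(n_coef)
    scale = np.zeros(n_coef)
    scale[1:] = freqs[1:] ** (-beta / 2.0)
    x = np.fft.irfft(coef * scale, n=n)
    x -= x.mean()
    return x / x.std()


def generate_sweep(config: SweepConfig) -> tuple[list[VoltageSeries], GroundTruth]:
    """Generate one synthetic sweep: all series plus their ground truth.

    Per-series seeds are drawn once from ``config.seed`` (bounded below
    2³¹), so the file set is a deterministic function of the config alone.
    """
    base_rng = np.random.default_rng(config.seed)
    n_series = len(config.temperatures) * config.n_replicates
    seeds = base_rng.integers(0, _MAX_SEED, size=n_series)
    betas = config.beta_profile()
    t = np.arange(config.n_samples) / config.sampling_rate

    series_list, records = [], []
    k = 0
    for temp, beta_t in zip(config.temperatures, betas):
        for rep in range(config.n_replicates):
            rng = np.random.default_rng(int(seeds[k]))
            x = config.signal_sd * colored_noise(config.n_samples, float(beta_t), rng)
            if config.oscillation is not None:
                osc = config.oscillation
                x = x + osc.amplitude * np.exp(-osc.damping * t) * np.sin(
                    2 * np.pi * osc.frequency * t
                )
            if config.sensor_noise_sd > 0:
                x = x + config.sensor_noise_sd * rng.standard_normal(config.n_samples)
            label = f"T{temp:05.2f}C_r{rep}"
            series_list.append(
                VoltageSeries(
                    x,
                    sampling_rate=config.sampling_rate,
                    temperature=float(temp),
                    replicate_id=rep,
                    label=label,
                )
            )
            records.append(
                {
                    "label": label,
                    "temperature": float(temp),
                    "replicate_id": rep,
                    "beta_true": float(beta_t),
                    "seed": int(seeds[k]),
                }
            )
            k += 1
    truth = GroundTruth(config=config, per_series=pd.DataFrame(records))
    return series_list, truth


def write_sweep(series_list, truth: GroundTruth, out_dir) -> Path:
    """Write a sweep as series files + manifest + ground-truth JSON.

    Returns the manifest path.  File layout matches what
    :func:`dynent.signal_io.read_series` expects.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    entries = []
    for s in series_list:
        fname = f"{s.label}.csv"
        write_series(s, out / fname)
        entries.append(
            {
                "series_path": fname,
                "temperature_C": s.temperature,
                "replicate_id": s.replicate_id,
            }
        )
    manifest_path = out / "manifest.csv"
    write_manifest(pd.DataFrame(entries), manifest_path)
    truth.to_json(out / "ground_truth.json")
    return manifest_path
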