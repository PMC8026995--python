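"""Per-series extraction of the full dynamic-measure set.

One call turns a voltage recording into the row of numbers the temperature
profiler consumes: spectral signature, Hurst family, embedding delays and
dimension, largest Lyapunov exponent and the two dynamic entropies, together
with every convention (detrend mode, (m, r), fit ranges) that produced them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict, field

import numpy as np
import pandas as pd

from . import entropy as _entropy
from .lyapunov import max_lyapunov
from .rescaled_range import dfa_alpha, hurst_family
from .signal_io import DetrendSpec, VoltageSeries, detrend
from .spectral import spectral_signature
from .state_space import acf_delay, ami_delay, embed, embedding_dimension

__all__ = ["MeasureSet", "measure_series", "measure_sweep", "MEASURE_GROUPS"]

#: Selectable measure groups (``which`` argument of :func:`measure_series`).
MEASURE_GROUPS = ("spectral", "hurst", "embedding", "lyapunov", "entropy")


@dataclass
class MeasureSet:
    """All dynamic measures of one series; unavailable entries are NaN."""

    label: str = ""
    temperature: float = np.nan
    replicate_id: int = 0
    sampling_rate: float = np.nan
    beta: float = np.nan
    stderr_beta: float = np.nan
    h_simple: float = np.nan
    h_corrected_rs: float = np.nan
    h_empirical: float = np.nan
    h_corrected_empirical: float = np.nan
    h_theoretical: float = np.nan
    dfa_alpha: float = np.nan
    delay_acf: float = np.nan
    delay_ami: float = np.nan
    embedding_dim: float = np.nan
    lambda_max: float = np.nan
    lambda_per_second: float = np.nan
    s_a: float = np.nan
    s_s: float = np.nan
    entropy_m: float = np.nan
    entropy_r: float = np.nan
    detrend_mode: str = "linear"

    def to_dict(self) -> dict:
        return asdict(self)


def measure_series(
    series: VoltageSeries,
    detrend_spec: DetrendSpec | None = None,
    which: tuple[str, ...] = MEASURE_GROUPS,
    m: int = 2,
    r: float = 0.2,
    max_embedding_dim: int = 12,
    lyapunov_fit_range: tuple[int, int] | None = None,
) -> MeasureSet:
    """Compute the selected dynamic measures for one recording.

    The series is detrended first (default: linear).  ``which`` selects
    measure groups so that cheap profile runs can skip the expensive
    state-space stages.  The Lyapunov estimate uses the AMI delay and the
    FNN embedding dimension; embedding failures leave NaN entries rather
    than aborting the sweep.
    """
    bad = set(which) - set(MEASURE_GROUPS)
    if bad:
        raise ValueError(f"unknown measure groups {sorted(bad)}")
    spec = detrend_spec or DetrendSpec()
    x = detrend(series, spec)
    out = MeasureSet(
        label=series.label,
        temperature=np.nan if series.temperature is None else float(series.temperature),
        replicate_id=series.replicate_id,
        sampling_rate=series.sampling_rate,
        detrend_mode=spec.mode,
    )
    if "spectral" in which:
        sf = spectral_signature(x)
        out.beta, out.stderr_beta = sf.beta, sf.stderr_beta
    if "hurst" in which:
        h = hurst_family(x)
        out.h_simple = h.h_simple
        out.h_corrected_rs = h.h_corrected_rs
        out.h_empirical = h.h_empirical
        out.h_corrected_empirical = h.h_corrected_empirical
        out.h_theoretical = h.h_theoretical
        out.dfa_alpha = dfa_alpha(x)
    if "embedding" in which or "lyapunov" in which:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # delay/FNN fallbacks are recorded as values
            out.delay_acf = acf_delay(x)
            out.delay_ami = ami_delay(x)
            out.embedding_dim = embedding_dimension(
                x, delay=int(out.delay_ami), max_dim=max_embedding_dim
            )
    if "lyapunov" in which:
        try:
            att = embed(x, int(out.embedding_dim), int(out.delay_ami))
            est = max_lyapunov(att, fit_range=lyapunov_fit_range)
            out.lambda_max = est.lambda_per_sample
            out.lambda_per_second = est.lambda_per_second
        except ValueError:
            pass  # too short / no pairs: leave NaN
    if "entropy" in which:
        out.s_a = _entropy.approximate_entropy(x, m=m, r=r)
        out.s_s = _entropy.sample_entropy(x, m=m, r=r)
        out.entropy_m, out.entropy_r = m, r
    return out


def measure_sweep(
    series_list,
    detrend_spec: DetrendSpec | None = None,
    which: tuple[str, ...] = MEASURE_GROUPS,
    **kwargs,
) -> pd.DataFrame:
    """Measure every series of a sweep; one row per recording."""
    rows = [
        measure_series(s, detrend_spec=detrend_spec, which=which, **kwargs).to_dict()
        for s in series_list
    ]
    return pd.DataFrame(rows)
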