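"""Approximate and sample entropy (the dynamic entropies S_a and S_s).

Both statistics gauge the regularity of a series by counting templates of
length m that stay within a Chebyshev tolerance r of each other and asking
how often such matches survive extension to length m + 1.  Approximate
entropy (Pincus) includes self-matches; sample entropy (Richman–Moorman)
excludes them and is the less length-dependent of the two.  Low values mean
deterministic, predictable dynamics; high values randomness.

The O(N²) pair counts are numba-compiled; with the standard m = 2,
r = 0.2·SD convention a 5000-sample series evaluates in tens of
milliseconds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .signal_io import VoltageSeries

__all__ = ["EntropyEstimate", "approximate_entropy", "sample_entropy", "entropy_pair"]

#: Sentinel returned by sample entropy when no template pair extends
#: (−log of zero); callers treat it as missing.
NO_MATCH_SENTINEL = np.inf


def _as_values(x) -> np.ndarray:
    if isinstance(x, VoltageSeries):
        return x.samples
    return np.asarray(x, dtype=float)


@dataclass(frozen=True)
class EntropyEstimate:
    """ApEn/SampEn pair with the (m, r) convention that produced it."""

    s_a: float
    s_s: float
    m: int
    r: float
    r_absolute: float

    def __post_init__(self) -> None:
        if self.s_a < 0 and not np.isclose(self.s_a, 0.0, atol=1e-12):
            raise ValueError("approximate entropy must be >= 0")
        if self.m < 1 or self.r_absolute <= 0:
            raise ValueError("need m >= 1 and a positive tolerance")

    @property
    def no_match(self) -> bool:
        """True when sample entropy hit the no-extension sentinel."""
        return not np.isfinite(self.s_s)


def _resolve_tolerance(x: np.ndarray, r: float, relative: bool) -> float:
    if r <= 0:
        raise ValueError("tolerance r must be positive")
    if not relative:
        return float(r)
    sd = x.std()
    if sd == 0:
        raise ValueError("relative tolerance undefined for zero-SD series")
    return float(r * sd)


@njit(cache=False)
def _phi_log_counts(x, m, r):
    """Mean log of ApEn match frequencies C_i^m(r), self-matches included."""
    n = x.shape[0]
    n_templates = n - m + 1
    total = 0.0
    for i in range(n_templates):
        count = 0
        for j in range(n_templates):
            match = True
            for k in range(m):
                d = abs(x[i + k] - x[j + k])
                if d > r:
                    match = False
                    break
            if match:
                count += 1
        total += np.log(count / n_templates)
    return total / n_templates


@njit(cache=False)
def _sampen_counts(x, m, r):
    """(B, A): m- and (m+1)-template match pair counts, no self-matches."""
    n = x.shape[0]
    n_templates = n - m  # same template count for both lengths
    b_count = 0
    a_count = 0
    for i in range(n_templates):
        for j in range(i + 1, n_templates):
            match = True
            for k in range(m):
                if abs(x[i + k] - x[j + k]) > r:
                    match = False
                    break
            if match:
                b_count += 1
                if abs(x[i + m] - x[j + m]) <= r:
                    a_count += 1
    return b_count, a_count


def approximate_entropy(
    series: VoltageSeries | np.ndarray,
    m: int = 2,
    r: float = 0.2,
    relative: bool = True,
) -> float:
    """Approximate entropy Φ^m(r) − Φ^{m+1}(r) (Pincus convention).

    ``r`` is a fraction of the series SD when ``relative`` (the default);
    pass ``relative=False`` for an absolute tolerance in signal units.
    Chebyshev distance; self-matches included, so the result is finite and
    non-negative (0 for a constant series).
    """
    x = _as_values(series)
    if m < 1:
        raise ValueError("template length m must be >= 1")
    if x.size < m + 2:
        raise ValueError(f"need at least m + 2 = {m + 2} samples, got {x.size}")
    r_abs = _resolve_tolerance(x, r, relative)
    return float(_phi_log_counts(x, m, r_abs) - _phi_log_counts(x, m + 1, r_abs))


def sample_entropy(
    series: VoltageSeries | np.ndarray,
    m: int = 2,
    r: float = 0.2,
    relative: bool = True,
) -> float:
    """Sample entropy −log(A/B) (Richman–Moorman convention).

    B counts Chebyshev-matching template pairs of length m and A those of
    length m + 1 over the same N − m templates, self-matches excluded.
    Returns ``inf`` (a flagged sentinel, see ``NO_MATCH_SENTINEL``) when no
    m-match extends; raises when there is no m-match at all.
    """
    x = _as_values(series)
    if m < 1:
        raise ValueError("template length m must be >= 1")
    if x.size < m + 2:
        raise ValueError(f"need at least m + 2 = {m + 2} samples, got {x.size}")
    r_abs = _resolve_tolerance(x, r, relative)
    b_count, a_count = _sampen_counts(x, m, r_abs)
    if b_count == 0:
        raise ValueError("no template matches at length m; increase r")
    if a_count == 0:
        return NO_MATCH_SENTINEL
    return float(-np.log(a_count / b_count))


def entropy_pair(
    series: VoltageSeries | np.ndarray,
    m: int = 2,
    r: float = 0.2,
    relative: bool = True,
) -> EntropyEstimate:
    """Convenience: both entropies with their recorded (m, r) convention."""
    x = _as_values(series)
    r_abs = _resolve_tolerance(x, r, relative)
    return EntropyEstimate(
        s_a=approximate_entropy(x, m=m, r=r, relative=relative),
        s_s=sample_entropy(x, m=m, r=r, relative=relative),
        m=m,
        r=r if relative else r_abs,
        r_absolute=r_abs,
    )
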