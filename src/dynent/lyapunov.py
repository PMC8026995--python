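"""Largest Lyapunov exponent via mean neighbour-divergence curves.

The largest Lyapunov exponent Λ is the asymptotic exponential rate at which
initially close state-space trajectories separate; Λ > 0 signals chaos,
Λ < 0 contraction onto a stable orbit.  The estimator is the Rosenstein
procedure: each attractor point is paired with its nearest neighbour outside
a Theiler exclusion window, the log distance of every pair is followed
forward in time, and Λ is the early-time slope of the averaged curve.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .state_space import Attractor, _nearest_excluding

__all__ = ["LyapunovEstimate", "max_lyapunov"]

_LOG_FLOOR = 1e-12  # distance floor before taking logs


@dataclass(frozen=True)
class LyapunovEstimate:
    """Largest-Lyapunov estimate with its divergence curve.

    ``lambda_per_sample`` is the log-distance slope per divergence step;
    ``lambda_per_second`` rescales by the sampling rate.
    """

    lambda_per_sample: float
    lambda_per_second: float
    fit_range: tuple[int, int]
    n_pairs: int
    divergence_curve: np.ndarray

    def __post_init__(self) -> None:
        lo, hi = self.fit_range
        if not (0 <= lo < hi < len(self.divergence_curve)):
            raise ValueError("fit_range must lie within the divergence curve")
        if self.n_pairs < 10:
            raise ValueError(f"too few neighbour pairs ({self.n_pairs}); need >= 10")

    @property
    def lambda_max(self) -> float:
        """Per-sample value (the primary estimate)."""
        return self.lambda_per_sample

    def to_text(self, path) -> None:
        """Write the divergence curve as delimited text (step, mean log distance)."""
        steps = np.arange(self.divergence_curve.size)
        np.savetxt(
            path,
            np.column_stack([steps, self.divergence_curve]),
            delimiter="\t",
            header="step\tmean_log_distance",
        )


def max_lyapunov(
    attractor: Attractor,
    theiler_window: int | None = None,
    n_steps: int = 20,
    fit_range: tuple[int, int] | None = None,
) -> LyapunovEstimate:
    """Rosenstein largest-Lyapunov estimate from a reconstructed attractor.

    Parameters
    ----------
    attractor : Attractor
        Reconstructed trajectory (>= 200 points).
    theiler_window : int, optional
        Temporal exclusion for neighbour pairing; defaults to the
        attractor's delay.
    n_steps : int
        Length of the divergence curve (steps 0..n_steps).
    fit_range : (first, last), optional
        Inclusive step range for the slope fit; default (1, 10).

    Notes
    -----
    ``divergence_curve[k]`` is the mean natural-log distance of neighbour
    pairs after ``k`` steps, averaged over pairs whose trajectories extend
    the full ``n_steps`` so every curve point uses the same pairs.
    """
    pts = attractor.points
    n = pts.shape[0]
    if n < 200:
        raise ValueError(f"max_lyapunov needs >= 200 attractor points, got {n}")
    if theiler_window is None:
        theiler_window = attractor.delay
    if theiler_window < 0:
        raise ValueError("theiler_window must be >= 0")
    if fit_range is None:
        fit_range = (1, min(10, n_steps))
    lo, hi = int(fit_range[0]), int(fit_range[1])
    if not (0 <= lo < hi <= n_steps):
        raise ValueError(f"fit_range {fit_range} outside divergence curve 0..{n_steps}")

    n_follow = n - n_steps
    if n_follow < 2:
        raise ValueError("attractor too short for the requested n_steps")
    base = pts[:n_follow]
    neigh, valid = _nearest_excluding(base, theiler_window)
    i_idx = np.nonzero(valid)[0]
    j_idx = neigh[i_idx]
    keep = j_idx < n_follow  # neighbour must also have n_steps of future
    i_idx, j_idx = i_idx[keep], j_idx[keep]
    if i_idx.size < 10:
        raise ValueError(f"only {i_idx.size} valid neighbour pairs; need >= 10")

    curve = np.empty(n_steps + 1)
    for k in range(n_steps + 1):
        d = np.linalg.norm(pts[i_idx + k] - pts[j_idx + k], axis=1)
        curve[k] = np.mean(np.log(np.maximum(d, _LOG_FLOOR)))

    steps = np.arange(lo, hi + 1)
    slope = float(np.polyfit(steps, curve[lo : hi + 1], 1)[0])
    return LyapunovEstimate(
        lambda_per_sample=slope,
        lambda_per_second=slope * attractor.sampling_rate,
        fit_range=(lo, hi),
        n_pairs=int(i_idx.size),
        divergence_curve=curve,
    )
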