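"""Delay-coordinate state-space reconstruction.

Takens embedding maps a scalar series onto vectors
(x_t, x_{t+τ}, …, x_{t+(m−1)τ}).  The delay τ is chosen either from the
autocorrelation function (first drop below 1/e) or from the first local
minimum of the average mutual information; the dimension m from the false
nearest-neighbour criterion.  A sphericity diagnostic quantifies attractor
anisotropy — the collapse of an isotropic 3-D cloud onto a planar ring shows
up as the smallest/largest second-moment eigenvalue ratio falling to zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .signal_io import VoltageSeries

__all__ = [
    "EmbeddingSpec",
    "Attractor",
    "acf_delay",
    "ami_delay",
    "average_mutual_information",
    "embedding_dimension",
    "embed",
    "sphericity",
]


def _as_values(x) -> np.ndarray:
    if isinstance(x, VoltageSeries):
        return x.samples
    return np.asarray(x, dtype=float)


@dataclass(frozen=True)
class EmbeddingSpec:
    """Embedding parameters: both delay candidates, dimension, Theiler window."""

    delay_acf: int
    delay_ami: int
    embedding_dim: int
    theiler_window: int

    def __post_init__(self) -> None:
        if min(self.delay_acf, self.delay_ami) < 1 or self.embedding_dim < 1:
            raise ValueError("delays and embedding_dim must be >= 1")
        if self.theiler_window < max(self.delay_acf, self.delay_ami):
            raise ValueError("theiler_window must be >= the delay used")

    def delay(self, which: str = "ami") -> int:
        if which not in ("acf", "ami"):
            raise ValueError("which_delay must be 'acf' or 'ami'")
        return self.delay_ami if which == "ami" else self.delay_acf


@dataclass(frozen=True)
class Attractor:
    """Reconstructed phase-space trajectory (one delay vector per row)."""

    points: np.ndarray
    delay: int
    source_length: int
    sampling_rate: float = 1.0

    def __post_init__(self) -> None:
        pts = np.atleast_2d(np.asarray(self.points, dtype=float))
        expected = self.source_length - (pts.shape[1] - 1) * self.delay
        if pts.shape[0] != expected:
            raise ValueError(
                f"point count {pts.shape[0]} inconsistent with source length "
                f"{self.source_length}, dim {pts.shape[1]}, delay {self.delay}"
            )
        object.__setattr__(self, "points", pts)

    @property
    def embedding_dim(self) -> int:
        return self.points.shape[1]

    def __len__(self) -> int:
        return self.points.shape[0]

    def to_text(self, path) -> None:
        """Write the trajectory as delimited text, one point per row."""
        np.savetxt(path, self.points, delimiter="\t")


# ---------------------------------------------------------------------------
# delay selection
# ---------------------------------------------------------------------------


def autocorrelation(x: np.ndarray, max_lag: int) -> np.ndarray:
    """Biased-normalisation sample ACF for lags 0..max_lag."""
    x = np.asarray(x, dtype=float)
    x = x - x.mean()
    denom = np.dot(x, x)
    if denom == 0:
        raise ValueError("autocorrelation undefined for zero-variance series")
    return np.array([np.dot(x[: x.size - k], x[k:]) / denom for k in range(max_lag + 1)])


def acf_delay(series: VoltageSeries | np.ndarray, max_lag: int | None = None) -> int:
    """Smallest lag at which the ACF first falls below 1/e.

    Returns ``max_lag`` with a warning if the ACF never drops that far.
    """
    x = _as_values(series)
    if max_lag is None:
        max_lag = x.size // 10
    if not (0 < max_lag < x.size // 2):
        raise ValueError("max_lag must satisfy 0 < max_lag < N/2")
    acf = autocorrelation(x, max_lag)
    below = np.nonzero(acf[1:] < 1.0 / np.e)[0]
    if below.size == 0:
        warnings.warn(
            f"ACF never fell below 1/e within {max_lag} lags; returning max_lag",
            stacklevel=2,
        )
        return max_lag
    return int(below[0] + 1)


def average_mutual_information(
    series: VoltageSeries | np.ndarray, max_lag: int, n_bins: int = 16
) -> np.ndarray:
    """Histogram-based AMI I(x_t; x_{t+τ}) in nats for τ = 1..max_lag."""
    x = _as_values(series)
    lo, hi = x.min(), x.max()
    if lo == hi:
        raise ValueError("AMI undefined for constant series")
    edges = np.linspace(lo, hi, n_bins + 1)
    edges[-1] = np.nextafter(edges[-1], np.inf)
    out = np.empty(max_lag)
    for tau in range(1, max_lag + 1):
        joint, _, _ = np.histogram2d(x[:-tau], x[tau:], bins=(edges, edges))
        joint /= joint.sum()
        px = joint.sum(axis=1)
        py = joint.sum(axis=0)
        nz = joint > 0
        out[tau - 1] = np.sum(
            joint[nz] * (np.log(joint[nz]) - np.log(np.outer(px, py)[nz]))
        )
    return out


def ami_delay(
    series: VoltageSeries | np.ndarray, max_lag: int | None = None, n_bins: int = 16
) -> int:
    """Lag of the first local minimum of the average mutual information.

    Lag 1 counts as a minimum when AMI(1) <= AMI(2).  When no local minimum
    exists below ``max_lag`` the ACF delay is returned with a warning.
    """
    x = _as_values(series)
    if max_lag is None:
        max_lag = max(2, x.size // 10)
    ami = average_mutual_information(x, max_lag, n_bins=n_bins)
    if ami[0] <= ami[1]:
        return 1
    for tau in range(2, max_lag):
        if ami[tau - 2] > ami[tau - 1] < ami[tau]:
            return tau
    warnings.warn(
        f"no AMI local minimum within {max_lag} lags; falling back to ACF delay",
        stacklevel=2,
    )
    return acf_delay(x, max_lag)


# ---------------------------------------------------------------------------
# embedding
# ---------------------------------------------------------------------------


def embed(
    series: VoltageSeries | np.ndarray,
    embedding_dim: int,
    delay: int,
) -> Attractor:
    """Takens delay embedding: point i = (x_i, x_{i+τ}, …, x_{i+(m−1)τ})."""
    x = _as_values(series)
    m, tau = int(embedding_dim), int(delay)
    if m < 1 or tau < 1:
        raise ValueError("embedding_dim and delay must be >= 1")
    needed = (m - 1) * tau + 2
    if x.size < needed:
        raise ValueError(
            f"series of length {x.size} too short to embed at dim {m}, "
            f"delay {tau}; need at least {needed} samples"
        )
    n_pts = x.size - (m - 1) * tau
    pts = np.column_stack([x[k * tau : k * tau + n_pts] for k in range(m)])
    rate = series.sampling_rate if isinstance(series, VoltageSeries) else 1.0
    return Attractor(pts, delay=tau, source_length=x.size, sampling_rate=rate)


def embed_from_spec(
    series: VoltageSeries | np.ndarray, spec: EmbeddingSpec, which_delay: str = "ami"
) -> Attractor:
    return embed(series, spec.embedding_dim, spec.delay(which_delay))


def _nearest_excluding(pts: np.ndarray, theiler: int, n_query: int = 25):
    """Index of each point's nearest neighbour outside the Theiler window.

    Returns (neighbour indices, validity mask); points with no admissible
    neighbour among the ``n_query`` closest are marked invalid.
    """
    n = pts.shape[0]
    tree = cKDTree(pts)
    k = min(n, n_query)
    _, idx = tree.query(pts, k=k)
    neigh = np.full(n, -1)
    for i in range(n):
        for j in idx[i]:
            if abs(int(j) - i) > theiler:
                neigh[i] = j
                break
    return neigh, neigh >= 0


def false_nearest_fraction(
    x: np.ndarray,
    dim: int,
    delay: int,
    theiler: int,
    ratio_tol: float = 10.0,
    abs_tol: float = 2.0,
) -> float:
    """Kennel false-nearest-neighbour fraction going from ``dim`` to ``dim+1``.

    A neighbour is false when the extra coordinate either stretches the pair
    by more than ``ratio_tol`` relative to its distance in ``dim`` dimensions
    or pushes the (dim+1)-distance beyond ``abs_tol`` series standard
    deviations — the second criterion keeps stochastic series from
    spuriously "embedding".
    """
    att = embed(x, dim, delay)
    pts = att.points
    horizon = dim * delay  # index of the extra coordinate for each point
    n_usable = x.size - horizon
    pts = pts[:n_usable]
    neigh, valid = _nearest_excluding(pts, theiler)
    i_idx = np.nonzero(valid)[0]
    j_idx = neigh[i_idx]
    if i_idx.size == 0:
        raise ValueError("no usable neighbour pairs for FNN")
    d_m = np.linalg.norm(pts[i_idx] - pts[j_idx], axis=1)
    extra = np.abs(x[i_idx + horizon] - x[j_idx + horizon])
    d_m1 = np.hypot(d_m, extra)
    sd = x.std()
    # pairs at numerical-noise distance are recurrences of the same state:
    # genuine neighbours, not candidates for the ratio test
    genuine = d_m > 1e-9 * sd
    false = np.zeros(i_idx.size, dtype=bool)
    false[genuine] = (extra[genuine] / d_m[genuine] > ratio_tol) | (
        d_m1[genuine] / sd > abs_tol
    )
    return float(false.mean())


def embedding_dimension(
    series: VoltageSeries | np.ndarray,
    delay: int,
    max_dim: int = 12,
    fnn_threshold: float = 0.02,
    theiler_window: int | None = None,
    ratio_tol: float = 10.0,
    abs_tol: float = 2.0,
) -> int:
    """Smallest dimension whose false-nearest-neighbour fraction is < 2%.

    Returns ``max_dim`` with a warning when the criterion is never met
    (e.g. for stochastic series, which do not embed).
    """
    x = _as_values(series)
    if theiler_window is None:
        theiler_window = delay
    if x.size - (max_dim - 1) * delay < 100:
        raise ValueError(
            f"series of length {x.size} leaves fewer than 100 points at "
            f"dim {max_dim}, delay {delay}"
        )
    for dim in range(1, max_dim + 1):
        fnn = false_nearest_fraction(
            x, dim, delay, theiler_window, ratio_tol=ratio_tol, abs_tol=abs_tol
        )
        if fnn < fnn_threshold:
            return dim
    warnings.warn(
        f"FNN fraction never fell below {fnn_threshold:.0%} up to dim "
        f"{max_dim}; series may be stochastic",
        stacklevel=2,
    )
    return max_dim


def sphericity(attractor: Attractor) -> tuple[float, np.ndarray]:
    """Shape isotropy of the attractor point cloud.

    Returns ``(smallest/largest eigenvalue, eigenvalues descending)`` of the
    centred second-moment matrix.  1 is a perfectly isotropic cloud; 0 a
    flat (rank-deficient) one.  Invariant under rotation and global scaling.
    """
    pts = attractor.points
    if pts.shape[0] < pts.shape[1] + 1:
        raise ValueError("need at least embedding_dim + 1 points")
    centred = pts - pts.mean(axis=0)
    if not centred.any():
        raise ValueError("sphericity undefined: all points identical")
    second_moment = centred.T @ centred / pts.shape[0]
    eigvals = np.linalg.eigvalsh(second_moment)[::-1]
    return float(eigvals[-1] / eigvals[0]), eigvals
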