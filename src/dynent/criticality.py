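"""Critical-temperature localisation by Lorentzian resonance fits.

The physiological working point shows up as a resonance: plotted against bath
temperature T, the inverse dynamic entropies 1/S_a and 1/S_s, the negated
inverse Lyapunov exponent −1/Λ and the spectral signature β all peak near one
critical temperature T_c.  Each channel is fitted with a four-parameter
Lorentzian (Cauchy) curve

    y(T) = baseline + amplitude · γ² / ((T − T_c)² + γ²),

where γ is the half-width at half-maximum.  ``LorentzianModel`` /
``LorentzianResults`` follow the statsmodels model–results idiom: the model
holds the data, ``fit()`` performs multi-start nonlinear least squares and
returns a results object carrying estimates, standard errors, R² and a
``summary()`` table.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "MEASURE_COLUMNS",
    "CHANNELS",
    "SweepProfile",
    "build_profile",
    "invert_measure",
    "LorentzianModel",
    "LorentzianResults",
    "lorentz_fit",
    "localize_tc",
    "proportionality_check",
    "ProportionalityReport",
]

#: Measures aggregated into a sweep profile.
MEASURE_COLUMNS = ("beta", "h_empirical", "lambda_max", "s_a", "s_s")

#: Resonance channels: profile column, invert?, negate?
CHANNELS = {
    "inv_s_a": ("s_a", True, False),
    "inv_s_s": ("s_s", True, False),
    "neg_inv_lambda": ("lambda_max", True, True),
    "beta": ("beta", False, False),
}
_CHANNEL_ALIASES = {
    "1/s_a": "inv_s_a",
    "1/s_s": "inv_s_s",
    "-1/lambda": "neg_inv_lambda",
    "beta": "beta",
}

#: Division guard for inverse measures.
DEFAULT_INVERSION_FLOOR = 1e-6

#: An R² below this triggers a "no resonance" warning.
WEAK_FIT_R2 = 0.2


def _lorentzian(x, t_c, gamma, amplitude, baseline):
    return baseline + amplitude * gamma**2 / ((x - t_c) ** 2 + gamma**2)


# ---------------------------------------------------------------------------
# profiles
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SweepProfile:
    """Per-temperature replicate means/SDs of the dynamic measures.

    ``table`` is indexed by strictly increasing temperature and holds, per
    measure in :data:`MEASURE_COLUMNS`, columns ``<m>_mean``, ``<m>_sd`` and
    ``<m>_n`` (replicates contributing after sentinel exclusion).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table.index.to_numpy(dtype=float)
        if t.size < 4:
            raise ValueError(
                f"a sweep profile needs >= 4 temperatures (Lorentzian has 4 "
                f"parameters), got {t.size}"
            )
        if np.any(np.diff(t) <= 0):
            raise ValueError("profile temperatures must be strictly increasing")

    @property
    def temperatures(self) -> np.ndarray:
        return self.table.index.to_numpy(dtype=float)

    def mean(self, measure: str) -> np.ndarray:
        return self.table[f"{measure}_mean"].to_numpy(dtype=float)

    def sd(self, measure: str) -> np.ndarray:
        return self.table[f"{measure}_sd"].to_numpy(dtype=float)

    def n(self, measure: str) -> np.ndarray:
        return self.table[f"{measure}_n"].to_numpy(dtype=int)

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index_label="temperature_C")


def build_profile(measures: pd.DataFrame | Iterable) -> SweepProfile:
    """Aggregate per-series measures into a temperature profile.

    ``measures`` is a measure table (one row per series) with a
    ``temperature`` column and the columns of :data:`MEASURE_COLUMNS`;
    anything with a ``to_frame``-able mapping per element is accepted.
    Non-finite entries (e.g. the sample-entropy no-match sentinel) are
    excluded per cell, with the surviving count recorded; SDs use the sample
    (ddof=1) convention.
    """
    if not isinstance(measures, pd.DataFrame):
        measures = pd.DataFrame([vars(m) if hasattr(m, "__dict__") else m for m in measures])
    if "temperature" not in measures.columns:
        raise ValueError("measure table needs a 'temperature' column")
    rows = {}
    for temp, group in measures.groupby("temperature", sort=True):
        row = {}
        for col in MEASURE_COLUMNS:
            if col in group.columns:
                vals = pd.to_numeric(group[col], errors="coerce").to_numpy(dtype=float)
                vals = vals[np.isfinite(vals)]
            else:
                vals = np.array([])
            row[f"{col}_mean"] = vals.mean() if vals.size else np.nan
            row[f"{col}_sd"] = vals.std(ddof=1) if vals.size > 1 else (0.0 if vals.size else np.nan)
            row[f"{col}_n"] = vals.size
        rows[float(temp)] = row
    table = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    return SweepProfile(table)


def invert_measure(
    values: Sequence[float],
    floor: float = DEFAULT_INVERSION_FLOOR,
    negate: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Elementwise guarded reciprocal 1 / max(|v|, floor).

    ``negate=True`` applies the −1/Λ convention for the Lyapunov channel:
    the result is −sign(v)/max(|v|, floor), so stable (negative-Λ) dynamics
    yield a positive peak.  Returns ``(inverted, flagged)`` where ``flagged``
    marks entries clipped by the floor.
    """
    if floor <= 0:
        raise ValueError("floor must be positive")
    v = np.asarray(values, dtype=float)
    mag = np.abs(v)
    flagged = mag < floor
    inv = 1.0 / np.maximum(mag, floor)
    if negate:
        inv = -np.sign(np.where(v == 0, 1.0, v)) * inv
    return inv, flagged


# ---------------------------------------------------------------------------
# Lorentzian model / results
# ---------------------------------------------------------------------------

_PARAM_NAMES = ("t_c", "half_width", "amplitude", "baseline")


class LorentzianModel:
    """Four-parameter Lorentzian resonance model of y(T).

    Parameters
    ----------
    x : array
        Temperatures (°C), at least 4 points.
    y : array
        Channel values; must be finite.
    weights : array, optional
        Relative weights (e.g. inverse replicate variance); used as
        1/sqrt(w) residual scaling in the least-squares problem.
    """

    def __init__(self, x, y, weights=None):
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if x.shape != y.shape or x.ndim != 1:
            raise ValueError("x and y must be 1-D arrays of equal length")
        if x.size < 4:
            raise ValueError("Lorentzian fit needs at least 4 points")
        if not np.all(np.isfinite(x) & np.isfinite(y)):
            raise ValueError("x and y must be finite")
        order = np.argsort(x)
        self.x, self.y = x[order], y[order]
        if weights is not None:
            weights = np.asarray(weights, dtype=float)[order]
            if np.any(weights <= 0) or not np.all(np.isfinite(weights)):
                raise ValueError("weights must be positive and finite")
        self.weights = weights

    @classmethod
    def from_profile(cls, profile: SweepProfile, channel: str,
                     floor: float = DEFAULT_INVERSION_FLOOR, weighted: bool = False):
        """Build the model for one resonance channel of a sweep profile.

        Inverse channels go through :func:`invert_measure`; missing profile
        cells are dropped pointwise.  ``weighted=True`` uses inverse
        variance of the (delta-method propagated) channel means.
        """
        channel = _CHANNEL_ALIASES.get(channel, channel)
        if channel not in CHANNELS:
            raise ValueError(f"unknown channel {channel!r}; choose from {sorted(CHANNELS)}")
        measure, inverted, negate = CHANNELS[channel]
        t = profile.temperatures
        mean = profile.mean(measure)
        keep = np.isfinite(mean)
        t, mean = t[keep], mean[keep]
        if t.size < 4:
            raise ValueError(f"channel {channel}: fewer than 4 usable temperatures")
        if inverted:
            y, _ = invert_measure(mean, floor=floor, negate=negate)
        else:
            y = mean
        weights = None
        if weighted:
            sd = profile.sd(measure)[keep]
            n = np.maximum(profile.n(measure)[keep], 1)
            var_mean = sd**2 / n
            if inverted:  # var(1/v) ≈ var(v) / v^4
                var_mean = var_mean / np.maximum(np.abs(mean), floor) ** 4
            if np.all(var_mean > 0):
                weights = 1.0 / var_mean
        model = cls(t, y, weights=weights)
        model.channel = channel
        return model

    def predict(self, params, x=None):
        x = self.x if x is None else np.asarray(x, dtype=float)
        return _lorentzian(x, *params)

    def _initial_guesses(self, n_starts: int, rng: np.random.Generator):
        x, y = self.x, self.y
        span = x[-1] - x[0]
        baseline0 = float(y.min())
        amp0 = float(y.max() - y.min()) or 1.0
        t_c0 = float(x[np.argmax(y)])
        above = x[y > baseline0 + 0.5 * amp0]
        gamma0 = max(0.5 * (above.max() - above.min()), span / len(x)) if above.size else span / 4
        guesses = [(t_c0, gamma0, amp0, baseline0)]
        for _ in range(n_starts - 1):
            guesses.append(
                (
                    t_c0 + rng.uniform(-0.25, 0.25) * span,
                    gamma0 * rng.uniform(0.3, 3.0),
                    amp0 * rng.uniform(0.5, 2.0),
                    baseline0 + rng.uniform(-0.5, 0.5) * amp0,
                )
            )
        return guesses

    def fit(self, n_starts: int = 5, seed: int = 0, max_nfev: int = 5000) -> "LorentzianResults":
        """Multi-start weighted least squares; best-residual start wins."""
        x, y = self.x, self.y
        span = x[-1] - x[0]
        sigma = None if self.weights is None else 1.0 / np.sqrt(self.weights)
        bounds = (
            [x[0] - 5.0, 1e-8, -np.inf, -np.inf],
            [x[-1] + 5.0, 10.0 * span, np.inf, np.inf],
        )
        rng = np.random.default_rng(seed)
        best = None
        failures = []
        for guess in self._initial_guesses(n_starts, rng):
            guess = np.clip(guess, bounds[0], bounds[1])
            try:
                popt, pcov = curve_fit(
                    _lorentzian, x, y, p0=guess, sigma=sigma,
                    bounds=bounds, max_nfev=max_nfev,
                    xtol=1e-12, ftol=1e-12, gtol=1e-12,
                )
            except (RuntimeError, ValueError) as exc:
                failures.append(str(exc))
                continue
            resid = y - _lorentzian(x, *popt)
            ssr = float(resid @ resid)
            if best is None or ssr < best[0]:
                best = (ssr, popt, pcov)
        if best is None:
            raise RuntimeError(
                "Lorentzian fit failed to converge from any start: "
                + "; ".join(failures[:3])
            )
        ssr, popt, pcov = best
        sst = float(np.sum((y - y.mean()) ** 2))
        r_squared = 1.0 - ssr / sst if sst > 0 else 0.0
        peak_span = float(y.max() - y.min())
        y_error = float(np.sqrt(ssr / y.size) / peak_span) if peak_span > 0 else 0.0
        results = LorentzianResults(
            model=self,
            params=dict(zip(_PARAM_NAMES, (float(p) for p in popt))),
            bse=dict(zip(_PARAM_NAMES, np.sqrt(np.abs(np.diag(pcov))).astype(float))),
            rsquared=r_squared,
            y_error=y_error,
            ssr=ssr,
            n_starts=n_starts,
            channel=getattr(self, "channel", None),
        )
        amp, amp_se = results.params["amplitude"], results.bse["amplitude"]
        insignificant = np.isfinite(amp_se) and amp_se > 0 and abs(amp) < 2 * amp_se
        if r_squared < WEAK_FIT_R2 or insignificant:
            warnings.warn(
                f"no clear resonance: R² = {r_squared:.3f}, amplitude "
                f"{amp:.3g} ± {amp_se:.3g}",
                stacklevel=2,
            )
        return results


@dataclass(frozen=True)
class LorentzianResults:
    """Fitted Lorentzian resonance: estimates, uncertainties, diagnostics."""

    model: LorentzianModel
    params: dict
    bse: dict
    rsquared: float
    y_error: float
    ssr: float
    n_starts: int
    channel: str | None = None

    @property
    def t_c(self) -> float:
        return self.params["t_c"]

    @property
    def half_width(self) -> float:
        """Half-width at half-maximum (HWHM), °C."""
        return self.params["half_width"]

    @property
    def fwhm(self) -> float:
        return 2.0 * self.params["half_width"]

    @property
    def amplitude(self) -> float:
        return self.params["amplitude"]

    @property
    def baseline(self) -> float:
        return self.params["baseline"]

    def predict(self, x=None) -> np.ndarray:
        return self.model.predict(list(self.params.values()), x)

    def to_dict(self) -> dict:
        return {
            "channel": self.channel,
            "params": self.params,
            "stderr": {k: float(v) for k, v in self.bse.items()},
            "fwhm": self.fwhm,
            "r_squared": self.rsquared,
            "y_error": self.y_error,
            "half_width_convention": "HWHM",
            "weighted": self.model.weights is not None,
        }

    def summary(self) -> str:
        lines = [
            "Lorentzian resonance fit",
            "=" * 54,
            f"channel: {self.channel or '-'}    n points: {self.model.x.size}"
            f"    weighted: {self.model.weights is not None}",
            f"R² = {self.rsquared:.4f}    y_error (RMS, peak-normalised) = {self.y_error:.4f}",
            "-" * 54,
            f"{'parameter':<14}{'estimate':>14}{'std err':>14}",
        ]
        units = {"t_c": "°C", "half_width": "°C (HWHM)", "amplitude": "", "baseline": ""}
        for name in _PARAM_NAMES:
            lines.append(
                f"{name:<14}{self.params[name]:>14.4f}{self.bse[name]:>14.4f}  {units[name]}"
            )
        lines.append("=" * 54)
        return "\n".join(lines)


def lorentz_fit(x, y, weights=None, n_starts: int = 5, seed: int = 0) -> LorentzianResults:
    """Functional wrapper: fit y(T) with a four-parameter Lorentzian."""
    return LorentzianModel(x, y, weights=weights).fit(n_starts=n_starts, seed=seed)


def localize_tc(
    profile: SweepProfile,
    channel: str = "inv_s_s",
    floor: float = DEFAULT_INVERSION_FLOOR,
    weighted: bool = False,
    n_starts: int = 5,
    seed: int = 0,
) -> LorentzianResults:
    """Localise the critical temperature on one resonance channel.

    Composes measure inversion (where the channel requires it) with the
    Lorentzian fit.  Channels: ``inv_s_a`` (1/S_a), ``inv_s_s`` (1/S_s),
    ``neg_inv_lambda`` (−1/Λ) and ``beta`` (fitted directly — β itself
    peaks at T_c).
    """
    model = LorentzianModel.from_profile(profile, channel, floor=floor, weighted=weighted)
    return model.fit(n_starts=n_starts, seed=seed)


# ---------------------------------------------------------------------------
# cross-measure proportionality
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ProportionalityReport:
    """Pairwise Pearson correlations among resonance channels over T."""

    correlations: pd.DataFrame
    threshold: float
    constant_channels: tuple[str, ...]

    @property
    def supported(self) -> bool:
        """True when every defined pairwise correlation meets the threshold."""
        c = self.correlations.to_numpy()
        off = c[~np.eye(c.shape[0], dtype=bool)]
        off = off[np.isfinite(off)]
        return bool(off.size) and bool(np.all(off >= self.threshold))

    def summary(self) -> str:
        lines = [
            "Cross-measure proportionality over the temperature grid",
            self.correlations.round(3).to_string(),
            f"threshold: {self.threshold}   supported: {self.supported}",
        ]
        if self.constant_channels:
            lines.append(f"constant channels (correlation undefined): {self.constant_channels}")
        return "\n".join(lines)


def proportionality_check(
    profile: SweepProfile,
    threshold: float = 0.7,
    floor: float = DEFAULT_INVERSION_FLOOR,
) -> ProportionalityReport:
    """Test the empirical relation β(T) ∝ 1/S_a(T) ≅ 1/S_s(T) ∝ −1/Λ(T).

    Computes Pearson correlations of the four channels over the temperature
    grid; the relation is flagged as supported when every defined pairwise
    correlation is at least ``threshold``.  Constant channels are reported
    rather than correlated.
    """
    if profile.temperatures.size < 5:
        raise ValueError("proportionality check needs >= 5 temperatures")
    cols = {}
    constant = []
    for name, (measure, inverted, negate) in CHANNELS.items():
        mean = profile.mean(measure)
        if inverted:
            vals, _ = invert_measure(mean, floor=floor, negate=negate)
        else:
            vals = mean.copy()
        vals[~np.isfinite(mean)] = np.nan
        finite = vals[np.isfinite(vals)]
        if finite.size and np.allclose(finite, finite[0]):
            constant.append(name)
        cols[name] = vals
    frame = pd.DataFrame(cols, index=profile.temperatures)
    corr = frame.corr(method="pearson")
    for name in constant:
        corr.loc[name, :] = np.nan
        corr.loc[:, name] = np.nan
    return ProportionalityReport(
        correlations=corr, threshold=threshold, constant_channels=tuple(constant)
    )
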