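# Methods

This note records the models, estimators, conventions and design choices
behind `dynent`, and what the synthetic benchmark does and does not show.

## Signal model and preprocessing

A recording is a uniformly sampled scalar voltage x_t (μV) at rate f_s
(default 4.1 Hz, N = 5000 samples ≈ 20 min), tagged with a bath temperature
(°C) and replicate index. Loading infers f_s from the median time step and
rejects files whose step jitter exceeds 1% of the median — the downstream
estimators all assume uniform sampling. Values are treated as μV throughout;
no unit conversion is performed.

Every measure is computed on a detrended series. Three variants are exposed
(mean removal, one least-squares line, contiguous piecewise-linear windows);
**linear is the default** — it is the common prestep of fluctuation analysis
and the safest against slow electrode drift. Piecewise windows default to
500 samples (10 windows at N = 5000); a trailing partial window is covered
by extrapolating the last full window's fit, which keeps the operation
idempotent. Which variant is used is recorded in every measure row.

## Spectral signature β

β is the negated OLS slope of log₁₀ PSD against log₁₀ frequency. The PSD is
a Welch estimate: Hann-tapered segments with 50% overlap, 8 segments by
default at N = 5000 (a single segment degenerates to the plain
periodogram). The default fit band excludes the 3 lowest nonzero bins
(biased by detrending and taper leakage) and the top octave (taper
roll-off); the band and bin count are recorded in the result. The estimator
is scale-invariant and, on spectrally synthesised colored noise at N = 5000,
unbiased to well within ±0.05 across β ∈ [0, 2].

## Rescaled-range Hurst family

R/S of a block is the range of the mean-adjusted cumulative sum divided by
the block standard deviation (population convention, per the package's
two-point reference example; the effect of the sd convention on the
regressed exponents is below 0.005). The default block design follows the
classical procedure as implemented in the R ecosystem the study's numbers
come from: trim to the length OptN within 1% of N having the most divisors
≥ 50, and use every divisor of OptN in [50, OptN/2] as a block size. Five
exponents are reported:

- *empirical*: OLS slope of log₁₀ mean R/S vs log₁₀ block size;
- *corrected R/S*: same regression on R/S − E[R/S] + √(πn/2), where E[R/S]
  is the Anis–Lloyd expectation with the Peters (n−½)/n finite-size
  prefactor (exact gamma form below n = 340, Stirling limit above) — this
  is the estimator that is unbiased (0.5) for white noise at N = 5000;
- *corrected empirical*: empirical slope shifted by (theoretical − ½);
- *theoretical*: the slope E[R/S] itself produces over the same blocks — a
  function of the block design only; 0.530 at N = 5000;
- *simple*: the single-point log R/S / log N of the whole series, plus a
  separate midpoint-halving variant (`corrected_rs_halving`).

A DFA exponent (linear detrend per window, complete forward windows,
log-spaced scales 8..N/4) is computed as a covariate, not as a Hurst
replacement.

## State-space reconstruction

Embedding delay: the ACF rule returns the first lag below 1/e; the AMI rule
the first strict local minimum of a 16-equal-width-bin histogram mutual
information (lag 1 qualifies when AMI(1) ≤ AMI(2)), falling back to the ACF
delay with a warning when no minimum exists. Both delays are always
recorded; the AMI delay feeds the default pipeline. Embedding dimension:
Kennel false-nearest-neighbour criterion with distance-ratio threshold 10,
absolute-stretch threshold 2 series SDs (this second criterion is what
keeps stochastic series from spuriously "embedding"), Theiler exclusion
equal to the delay, and acceptance when the FNN fraction drops below 2%;
the cap (default 12) is returned with a warning otherwise. Neighbour pairs
closer than 1e-9 SD are exact state recurrences and are counted as true
neighbours — without this, a sine sampled commensurately with its period
degenerates. Note that such commensurate sampling makes FNN indeterminate
in principle (every state recurs exactly); benchmarks use incommensurate
periods.

Sphericity of an attractor is the smallest/largest eigenvalue ratio of the
centred second-moment matrix, with the full eigenvalue spectrum returned.
It is the package's quantitative proxy for the collapse of an isotropic
3-D phase volume onto a planar ring near criticality; no group-theoretic
classification is attempted. At 10⁴ points an isotropic Gaussian cloud
scores ≈ 0.94, not 1 — finite-sample eigenvalue spread bounds the ratio.

## Largest Lyapunov exponent

Rosenstein estimator: each point's nearest neighbour outside the Theiler
window (default: the delay) is tracked k = 0..n_steps forward; the curve of
mean log distance is fitted by OLS over a step range (default 1–10,
always recorded), restricted to pairs whose trajectories span the full
horizon so every curve point averages the same pairs. Both per-sample and
per-second values are reported because the study's printed magnitudes
(−14.04, −15.01) carry unstated units; matching them is explicitly not a
target. The estimator reproduces ln 2 on the fully chaotic logistic map
when fitted before the curve saturates (steps 1–7 at N = 5000; by step ~9
typical pair distances reach the attractor diameter).

## Dynamic entropies

ApEn(m, r) = Φ^m − Φ^{m+1} with self-matches included (Pincus); SampEn(m, r)
= −log(A/B) over the same N − m templates with self-matches excluded
(Richman–Moorman). Chebyshev distance; matches at distance exactly r count.
Defaults m = 2, r = 0.2 × SD of the detrended series — the standard
physiological-series convention; the study states neither, so exact numeric
reproduction of its entropy values is not possible and the (m, r) actually
used is recorded with every result. SampEn with B > 0 but A = 0 returns an
∞ sentinel (profiles drop it pointwise, with the replicate count recorded)
rather than raising, so sweep tables stay rectangular; B = 0 raises.
Strict monotonicity of SampEn in r is not a theorem (match counts are step
functions of r), but holds on all tested series.

## Temperature criticality

Per-temperature profiles hold replicate means and sample SDs per measure,
with non-finite sentinels excluded per cell. Channels: 1/S_a, 1/S_s,
−1/Λ (the negation makes stable dynamics a positive peak; a configurable
floor, default 1e-6, guards the reciprocal and is recorded), and β fitted
directly (it peaks at T_c itself).

The resonance model is the four-parameter Lorentzian
y(T) = b + a·γ²/((T − T_c)² + γ²) with a free baseline (the observed curves
do not fall to zero). γ is reported as the half-width at half-maximum, with
the FWHM also emitted — "half-width" in the source material is otherwise
ambiguous. Fitting is bounded trust-region least squares from a data-driven
start (T_c at the argmax, baseline at the minimum, γ from the half-maximum
span) plus 4 deterministically jittered restarts, best residual kept; tight
tolerances (1e-12) make the fit shift- and scale-equivariant to ~1e-8.
Reported diagnostics: parameter standard errors from the Jacobian
covariance, unweighted R², and y_error — the RMS residual after
peak-normalising y to [0, 1], a declared interpretation of the study's
unexplained y-error statistic. Inverse-replicate-variance weighting is
available but off by default: with two replicates the single-degree-of-
freedom variance estimates make weighted fits noisier. A fit whose R² is
below 0.2 or whose amplitude is within 2 standard errors of zero warns
"no clear resonance". B-spline smoothing is a display nicety in the source
material and never feeds any fit here.

The proportionality check computes Pearson correlations among the four
channels over the temperature grid and flags the relation
β ∝ 1/S_a ≅ 1/S_s ∝ −1/Λ as supported when every defined pairwise
correlation is ≥ 0.7 (configurable); constant channels are reported, not
correlated.

## Synthetic sweeps: what they emulate and what they don't

`SweepConfig` defaults encode the study design: 15 temperatures over
30–43 °C (the original range is unpublished), 2 replicate channels,
5000 samples at 4.1 Hz, sensor noise 0.1 μV (the instrument resolution),
signal SD 1 μV (a realistic few-times-resolution amplitude), and a spectral
exponent following an exactly Lorentzian profile from the saline-control
baseline 0.475 to a peak of 1.0 centred at 36.6 °C with HWHM 2.67 °C.
Colored noise is spectrally synthesised (independent complex-Gaussian
coefficients scaled by f^(−β/2)), unit-SD, and bit-reproducible; per-series
seeds are drawn once from the config seed, so a sweep is a pure function of
its config. An optional damped oscillation models a deterministic component.

The entropy minimum is induced *indirectly*: a higher β makes the series
smoother, which lowers SampEn/ApEn — the 1/f mechanism itself, not an
imposed entropy value. A consequence worth understanding before comparing
half-widths: the β → SampEn map is nonlinear (concave, accelerating
decline), so the resonance seen through 1/S_s is intrinsically *narrower*
than the generating β(T) profile — the pipeline recovers the generator's
centre to ±0.2 °C and its half-width on the β channel (2.7 ± 0.3 °C), but
the 1/S_s channel yields ≈ 1.8 °C for a generating 2.67 °C. The same
channel dependence appears in the study's own fits, whose S_a and S_s
half-widths differ by a similar factor.

What passing the synthetic benchmark does **not** show: the generator has
no electrochemistry, no haemodynamics, no slow drift beyond what detrending
removes, Gaussian amplitude statistics, and replicates that are
statistically exchangeable — real recordings need not be any of these.
Results on it validate the estimators and the profiler, not the biology.

## Problem sizes and numerical choices

Monte-Carlo scales used by the test-suite and the acceptance script — 100
seeds for spectral recovery, 50 simulated sweeps for the criticality
pipeline, 20 for the proportionality property — were chosen to put the
Monte-Carlo standard error of each reported mean well below the tolerance
it is compared at. Degenerate inputs are rejected with named minima
(series/blocks/scales too short), zero-variance series raise everywhere a
relative tolerance or correlation would be undefined, and all stochastic
behaviour — generators, fit restarts — is seed-controlled and recorded.

## Known limitations

- The study's per-series Table values (entropies, Lyapunov magnitudes,
  Hurst exponents of the actual recordings) are not reproducible without
  the unpublished recordings and the unpublished (m, r), embedding and unit
  conventions; the package documents them as reference outputs only.
- The FNN dimension and AMI delay are histogram/threshold heuristics; on
  short or strongly quantised series prefer scanning the diagnostics
  (`false_nearest_fraction`, `average_mutual_information`) over trusting
  the single returned integer.
- SampEn's ∞ sentinel biases a profile cell's replicate mean when it fires
  asymmetrically across replicates; cells where it fired are visible via
  the recorded replicate counts.
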