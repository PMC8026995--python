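# dynent

Nonlinear time-series analysis of extracellular ionic-flux voltage
recordings, and localisation of the critical (physiological) temperature at
which their dynamic entropy is minimal.

## The problem

A drop of blood (or any electrolyte in contact with a semiconductor sensor)
generates a fluctuating voltage signal from its extracellular ion fluxes.
Recorded across a sweep of bath temperatures, the *dynamics* of that signal
change character: near the physiological working point (~36.6 °C) the
fluctuations become maximally 1/f-correlated, regular and stable, so the
dynamic entropy — the entropy *rate* of the signal, estimated by approximate
entropy S_a and sample entropy S_s — passes through a minimum. Plotting the
inverse entropy S⁻¹(T), the negated inverse largest Lyapunov exponent
−Λ⁻¹(T), or the spectral signature β(T) against temperature therefore yields
a resonance curve whose centre is the critical temperature T_c.

`dynent` implements the full measurement chain for anyone analysing such
sweeps (or any uniformly sampled physiological voltage series):

- **signal_io** — two-column series files, sweep manifests, mean / linear /
  piecewise-linear detrending;
- **spectral** — Welch PSD and the spectral signature
  β = −d log₁₀ P / d log₁₀ f (β = 0 white, 1 pink, 2 Brownian);
- **rescaled_range** — the R/S Hurst family: simple, empirical,
  Anis–Lloyd-corrected, corrected-empirical and theoretical (finite-sample
  expected R/S) exponents, plus a DFA covariate;
- **state_space** — embedding delays from the ACF (first 1/e crossing) and
  the average mutual information (first local minimum), false-nearest-
  neighbour embedding dimension, Takens reconstruction, and a sphericity
  diagnostic for attractor anisotropy;
- **lyapunov** — Rosenstein largest-Lyapunov estimate from mean
  neighbour-divergence curves;
- **entropy** — approximate entropy (Pincus) and sample entropy
  (Richman–Moorman), numba-accelerated;
- **criticality** — temperature profiles, the statsmodels-style
  `LorentzianModel` / `LorentzianResults` pair fitting
  y(T) = baseline + amplitude·γ² / ((T − T_c)² + γ²)
  (γ = half-width at half-maximum), `localize_tc` for the four resonance
  channels, and the cross-measure proportionality check
  β(T) ∝ 1/S_a(T) ≅ 1/S_s(T) ∝ −1/Λ(T);
- **synthetic** — a sweep generator with known ground truth (colored noise
  whose spectral exponent follows an exactly Lorentzian temperature
  profile), so the whole pipeline is testable without laboratory data.

## Worked example

```python
import warnings; warnings.simplefilter("ignore")
from dynent import (SweepConfig, generate_sweep, measure_sweep,
                    build_profile, localize_tc, proportionality_check)

config = SweepConfig(seed=1)          # 15 temperatures x 2 replicates x 5000 samples @ 4.1 Hz
series, truth = generate_sweep(config)
table = measure_sweep(series, which=("entropy", "spectral"))
profile = build_profile(table)
fit = localize_tc(profile, "inv_s_s") # Lorentzian fit of 1/SampEn vs T
print(fit.summary())
```

```
Lorentzian resonance fit
======================================================
channel: inv_s_s    n points: 15    weighted: False
R² = 0.9959    y_error (RMS, peak-normalised) = 0.0199
------------------------------------------------------
parameter           estimate       std err
t_c                  36.6773        0.0332  °C
half_width            1.9117        0.0794  °C (HWHM)
amplitude             0.1140        0.0022  
baseline              0.4677        0.0017  
======================================================
```

The generator centred the resonance at 36.6 °C; the inverse-sample-entropy
channel recovers T_c = 36.68 ± 0.03 °C with an excellent fit (R² ≈ 1). The
fitted half-width (1.9 °C) is narrower than the generating β(T) half-width
(2.67 °C) because sample entropy responds nonlinearly to the spectral
exponent — see `docs/methods.md`. The proportionality report confirms the
channels co-vary:

```python
print(proportionality_check(profile).summary())
#                 inv_s_a  inv_s_s   beta
# inv_s_a           1.000    0.999  0.978
# inv_s_s           0.999    1.000  0.979
# beta              0.978    0.979  1.000
# threshold: 0.7   supported: True
```

The same pipeline is available from the shell:

```sh
dynent simulate --out sweep/ --seed 1
dynent measure  --manifest sweep/manifest.csv --out measures.csv
dynent profile  --measures measures.csv --out results/
```

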