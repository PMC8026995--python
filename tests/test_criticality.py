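import numpy as np
import pandas as pd
import pytest

from dynent import (
    LorentzianModel,
    SweepConfig,
    build_profile,
    generate_sweep,
    invert_measure,
    localize_tc,
    lorentz_fit,
    measure_sweep,
    proportionality_check,
)


def lorentz(x, t_c, gamma, amp, base):
    return base + amp * gamma**2 / ((x - t_c) ** 2 + gamma**2)


def profile_from_channels(temps, **channels):
    """Build a SweepProfile whose per-measure means are given directly."""
    rows = []
    for i, t in enumerate(temps):
        row = {"temperature": t}
        for name, values in channels.items():
            row[name] = values[i]
        rows.append(row)
    return build_profile(pd.DataFrame(rows))


class TestBuildProfile:
    def test_replicate_mean_and_sample_sd(self):
        tab = pd.DataFrame(
            {
                "temperature": [30.0, 30.0, 32.0, 32.0, 34.0, 34.0, 36.0, 36.0],
                "s_s": [1.0, 3.0, 2.0, 2.0, 2.0, 2.0, 2.0, 2.0],
            }
        )
        prof = build_profile(tab)
        assert prof.mean("s_s")[0] == pytest.approx(2.0)
        assert prof.sd("s_s")[0] == pytest.approx(np.sqrt(2.0))

    def test_sentinel_drops_replicate_count(self):
        tab = pd.DataFrame(
            {
                "temperature": [30.0, 30.0, 32.0, 32.0, 34.0, 34.0, 36.0, 36.0],
                "s_s": [1.0, np.inf, 2.0, 2.0, 2.0, 2.0, 2.0, 2.0],
            }
        )
        prof = build_profile(tab)
        assert prof.n("s_s")[0] == 1
        assert prof.mean("s_s")[0] == pytest.approx(1.0)
        assert prof.n("s_s")[1] == 2

    def test_fewer_than_four_temperatures_rejected(self):
        tab = pd.DataFrame({"temperature": [30.0, 32.0, 34.0], "s_s": [1, 2, 1]})
        with pytest.raises(ValueError, match=">= 4 temperatures"):
            build_profile(tab)

    def test_generator_round_trip_shape(self):
        config = SweepConfig(n_samples=256, seed=1)
        series, _ = generate_sweep(config)
        tab = measure_sweep(series, which=("entropy",))
        prof = build_profile(tab)
        assert prof.temperatures.size == 15


class TestInvertMeasure:
    def test_elementwise_reciprocal(self):
        inv, flagged = invert_measure([2.0, 4.0], floor=1e-6)
        np.testing.assert_allclose(inv, [0.5, 0.25])
        assert not flagged.any()

    def test_zero_clipped_to_floor_and_flagged(self):
        inv, flagged = invert_measure([0.0], floor=1e-6)
        assert inv[0] == pytest.approx(1e6)
        assert flagged[0]

    def test_lyapunov_negation_convention(self):
        # stable (negative) exponents must give a positive peak
        inv, _ = invert_measure([-14.04, -15.01], negate=True)
        np.testing.assert_allclose(inv, [1 / 14.04, 1 / 15.01])

    def test_floor_must_be_positive(self):
        with pytest.raises(ValueError):
            invert_measure([1.0], floor=0.0)


class TestLorentzFit:
    T = np.linspace(30.0, 43.0, 15)

    def test_noiseless_exact_recovery(self):
        y = lorentz(self.T, 36.6, 2.0, 1.0, 0.2)
        fit = lorentz_fit(self.T, y)
        assert fit.t_c == pytest.approx(36.6, abs=1e-6)
        assert fit.half_width == pytest.approx(2.0, abs=1e-6)
        assert fit.amplitude == pytest.approx(1.0, abs=1e-6)
        assert fit.baseline == pytest.approx(0.2, abs=1e-6)
        assert fit.rsquared == pytest.approx(1.0, abs=1e-8)
        assert fit.y_error == pytest.approx(0.0, abs=1e-8)

    def test_noisy_monte_carlo_centre_recovery(self):
        tcs = []
        for seed in range(40):
            noise = np.random.default_rng(seed).normal(0, 0.05, self.T.size)
            fit = lorentz_fit(self.T, lorentz(self.T, 36.6, 2.0, 1.0, 0.2) + noise)
            tcs.append(fit.t_c)
        assert np.mean(tcs) == pytest.approx(36.6, abs=0.1)

    def test_shift_equivariance(self):
        rng = np.random.default_rng(0)
        y = lorentz(self.T, 36.6, 2.0, 1.0, 0.2) + rng.normal(0, 0.05, self.T.size)
        f1 = lorentz_fit(self.T, y)
        f2 = lorentz_fit(self.T + 7.5, y)
        assert f2.t_c - f1.t_c == pytest.approx(7.5, abs=1e-8)
        assert f2.half_width == pytest.approx(f1.half_width, abs=1e-8)

    def test_scale_equivariance(self):
        rng = np.random.default_rng(0)
        y = lorentz(self.T, 36.6, 2.0, 1.0, 0.2) + rng.normal(0, 0.05, self.T.size)
        f1 = lorentz_fit(self.T, y)
        f2 = lorentz_fit(self.T, 3.7 * y)
        assert f2.t_c == pytest.approx(f1.t_c, abs=1e-8)
        assert f2.half_width == pytest.approx(f1.half_width, abs=1e-8)
        assert f2.rsquared == pytest.approx(f1.rsquared, abs=1e-8)
        assert f2.amplitude == pytest.approx(3.7 * f1.amplitude, rel=1e-7)
        assert f2.baseline == pytest.approx(3.7 * f1.baseline, rel=1e-7)

    def test_flat_profile_warns_zero_rsquared(self):
        with pytest.warns(UserWarning, match="no clear resonance"):
            fit = lorentz_fit(self.T, np.full(self.T.size, 2.5))
        assert fit.rsquared == pytest.approx(0.0, abs=1e-8)

    def test_weighted_fit_downweights_outlier(self):
        y = lorentz(self.T, 36.6, 2.0, 1.0, 0.2)
        y_out = y.copy()
        y_out[0] += 1.0  # corrupt one tail point
        w = np.ones(self.T.size)
        w[0] = 1e-6
        fit = lorentz_fit(self.T, y_out, weights=w)
        assert fit.t_c == pytest.approx(36.6, abs=1e-3)
        assert fit.half_width == pytest.approx(2.0, abs=1e-2)

    def test_summary_contains_estimates(self):
        fit = lorentz_fit(self.T, lorentz(self.T, 36.6, 2.0, 1.0, 0.2))
        text = fit.summary()
        assert "t_c" in text and "36.6" in text and "HWHM" in text

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="at least 4"):
            lorentz_fit([1.0, 2.0, 3.0], [1.0, 2.0, 1.0])


class TestLocalizeTc:
    T = np.linspace(30.0, 43.0, 15)

    def test_ground_truth_beta_profile_exact_recovery(self):
        # feeding the generator's exactly Lorentzian beta(T) through the
        # beta channel must return the generating parameters
        config = SweepConfig()
        beta = config.beta_profile()
        prof = profile_from_channels(config.temperatures, beta=beta)
        fit = localize_tc(prof, "beta")
        assert fit.t_c == pytest.approx(config.t_c_true, abs=1e-8)
        assert fit.half_width == pytest.approx(config.half_width_true, abs=1e-8)
        assert fit.rsquared == pytest.approx(1.0, abs=1e-10)

    def test_inverse_entropy_channel_inverts(self):
        s_s = 1.0 / lorentz(self.T, 36.6, 2.0, 1.0, 0.2)
        prof = profile_from_channels(self.T, s_s=s_s)
        fit = localize_tc(prof, "inv_s_s")
        assert fit.t_c == pytest.approx(36.6, abs=1e-6)
        assert fit.channel == "inv_s_s"

    def test_lambda_channel_negates(self):
        lam = -1.0 / lorentz(self.T, 36.6, 2.0, 1.0, 0.2)
        prof = profile_from_channels(self.T, lambda_max=lam)
        fit = localize_tc(prof, "neg_inv_lambda")
        assert fit.t_c == pytest.approx(36.6, abs=1e-6)

    def test_spec_style_channel_aliases(self):
        s_a = 1.0 / lorentz(self.T, 36.6, 2.0, 1.0, 0.2)
        prof = profile_from_channels(self.T, s_a=s_a)
        fit = localize_tc(prof, "1/s_a")
        assert fit.channel == "inv_s_a"

    def test_unknown_channel_rejected(self):
        prof = profile_from_channels(self.T, s_s=np.ones(15))
        with pytest.raises(ValueError, match="unknown channel"):
            localize_tc(prof, "entropy_rate")

    def test_missing_cells_dropped_pointwise(self):
        s_s = 1.0 / lorentz(self.T, 36.6, 2.0, 1.0, 0.2)
        s_s[3] = np.inf  # sentinel: excluded, not imputed
        prof = profile_from_channels(self.T, s_s=s_s)
        fit = localize_tc(prof, "inv_s_s")
        assert fit.t_c == pytest.approx(36.6, abs=1e-6)
        assert fit.model.x.size == 14


class TestProportionality:
    T = np.linspace(30.0, 43.0, 15)

    def _resonant_profile(self, flip_beta=False):
        peak = lorentz(self.T, 36.6, 2.0, 1.0, 0.2)
        beta = peak * 0.8
        if flip_beta:
            beta = -beta
        return profile_from_channels(
            self.T,
            beta=beta,
            s_a=1.0 / (2.0 * peak),
            s_s=1.0 / (1.5 * peak),
            lambda_max=-1.0 / (0.7 * peak),
        )

    def test_exactly_proportional_channels_correlate_perfectly(self):
        report = proportionality_check(self._resonant_profile())
        off = report.correlations.to_numpy()[~np.eye(4, dtype=bool)]
        np.testing.assert_allclose(off, 1.0, atol=1e-10)
        assert report.supported

    def test_negated_channel_anticorrelates(self):
        report = proportionality_check(self._resonant_profile(flip_beta=True))
        assert report.correlations.loc["beta", "inv_s_s"] == pytest.approx(-1.0)
        assert not report.supported

    def test_constant_channel_flagged(self):
        prof = profile_from_channels(
            self.T,
            beta=np.full(15, 0.5),
            s_s=1.0 / lorentz(self.T, 36.6, 2.0, 1.0, 0.2),
            s_a=1.0 / lorentz(self.T, 36.6, 2.0, 1.0, 0.2),
            lambda_max=-np.ones(15),
        )
        report = proportionality_check(prof)
        assert "beta" in report.constant_channels
        assert np.isnan(report.correlations.loc["beta", "inv_s_s"])

    def test_too_few_temperatures_rejected(self):
        prof = profile_from_channels(
            np.array([30.0, 33.0, 36.0, 39.0]), s_s=np.array([1.0, 0.5, 1.0, 1.2])
        )
        with pytest.raises(ValueError, match=">= 5"):
            proportionality_check(prof)


class TestModelResultsInterface:
    def test_model_from_profile_and_predict(self):
        T = np.linspace(30.0, 43.0, 15)
        s_s = 1.0 / lorentz(T, 36.6, 2.0, 1.0, 0.2)
        prof = profile_from_channels(T, s_s=s_s)
        model = LorentzianModel.from_profile(prof, "inv_s_s")
        res = model.fit()
        np.testing.assert_allclose(res.predict(), lorentz(T, 36.6, 2.0, 1.0, 0.2), atol=1e-6)
        d = res.to_dict()
        assert d["half_width_convention"] == "HWHM"
        assert d["fwhm"] == pytest.approx(2 * res.half_width)
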