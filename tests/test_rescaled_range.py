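import numpy as np
import pytest

from dynent import (
    colored_noise,
    corrected_rs_halving,
    default_block_sizes,
    dfa_alpha,
    expected_rescaled_range,
    hurst_family,
    rs_statistic,
    theoretical_hurst,
)

from conftest import make_series

# Reference values from an independent R implementation of the classical
# R/S procedure (pracma::hurstexp) on this exact series; small differences
# stem from the population-sd convention used here.
PRACMA_SERIES_ARGS = (2000, 0.8, 7)  # colored_noise(n, beta, seed)
PRACMA_REFERENCE = {
    "h_simple": 0.7164344874,
    "h_halving": 0.8164465958,
    "h_empirical": 0.8725394308,
    "h_corrected_rs": 0.8474065333,
    "h_theoretical": 0.5344697202,
}


class TestRsStatistic:
    def test_two_point_closed_form(self):
        # cumulative deviations (1, 0): range 1; population sd 1
        assert rs_statistic([1.0, -1.0]) == pytest.approx(1.0, abs=1e-12)

    def test_matches_hand_computation(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        dev = np.cumsum(x - x.mean())
        expected = (dev.max() - dev.min()) / x.std()
        assert rs_statistic(x) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("scale", [7.0, 0.001, 1e6])
    def test_scale_invariant(self, rng, scale):
        x = rng.standard_normal(64)
        assert rs_statistic(scale * x) == pytest.approx(rs_statistic(x), rel=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="zero-variance"):
            rs_statistic([3.0, 3.0, 3.0])


class TestExpectedRescaledRange:
    @pytest.mark.parametrize("n", [8, 64, 512])
    def test_matches_monte_carlo_expectation(self, n):
        # oracle: mean R/S of i.i.d. Gaussian blocks, sample-sd convention
        # (the convention under which the Anis–Lloyd formula is derived)
        rng = np.random.default_rng(7)
        vals = []
        for _ in range(20000):
            x = rng.standard_normal(n)
            dev = np.cumsum(x - x.mean())
            vals.append((dev.max() - dev.min()) / x.std(ddof=1))
        assert expected_rescaled_range(n) == pytest.approx(np.mean(vals), rel=0.01)

    def test_continuous_across_gamma_cutoff(self):
        # exact-gamma and Stirling branches agree near the switchover
        exact = expected_rescaled_range(340)
        asym_style = expected_rescaled_range(341)
        assert asym_style / exact == pytest.approx(
            np.sqrt(341 / 340), rel=5e-3
        )


class TestHurstFamily:
    def test_matches_r_reference_implementation(self):
        x = colored_noise(*PRACMA_SERIES_ARGS)
        h = hurst_family(x)
        assert h.h_theoretical == pytest.approx(PRACMA_REFERENCE["h_theoretical"], abs=1e-9)
        assert h.h_simple == pytest.approx(PRACMA_REFERENCE["h_simple"], abs=5e-3)
        assert h.h_empirical == pytest.approx(PRACMA_REFERENCE["h_empirical"], abs=5e-3)
        assert h.h_corrected_rs == pytest.approx(PRACMA_REFERENCE["h_corrected_rs"], abs=5e-3)
        assert corrected_rs_halving(x) == pytest.approx(PRACMA_REFERENCE["h_halving"], abs=5e-3)

    def test_theoretical_exponent_for_length_5000(self):
        # finite-size expectation exceeds the asymptotic 1/2
        assert theoretical_hurst(5000) == pytest.approx(0.530, abs=0.01)

    def test_theoretical_is_data_free_and_decays_to_half(self, rng):
        h1 = hurst_family(rng.standard_normal(5000))
        h2 = hurst_family(colored_noise(5000, 1.5, 3))
        assert h1.h_theoretical == h2.h_theoretical
        small = hurst_family(rng.standard_normal(5000), block_sizes=[8, 16, 32, 64])
        large = hurst_family(rng.standard_normal(5000), block_sizes=[256, 512, 1024, 2048])
        assert small.h_theoretical > large.h_theoretical > 0.5

    def test_white_noise_corrected_estimate_unbiased(self):
        vals = [
            hurst_family(np.random.default_rng(1000 + s).standard_normal(5000)).h_corrected_rs
            for s in range(30)
        ]
        assert np.mean(vals) == pytest.approx(0.5, abs=0.03)

    def test_persistent_noise_recovery(self):
        # fGn correspondence H = (beta + 1) / 2: exponent 0.6 -> H = 0.8
        vals = [
            hurst_family(colored_noise(5000, 0.6, 2000 + s)).h_empirical
            for s in range(30)
        ]
        assert np.mean(vals) == pytest.approx(0.8, abs=0.05)

    def test_affine_invariance(self, rng):
        x = rng.standard_normal(2048)
        h1 = hurst_family(x)
        h2 = hurst_family(3.7 * x - 11.0)
        for name in ("h_simple", "h_corrected_rs", "h_empirical",
                     "h_corrected_empirical", "h_theoretical"):
            assert getattr(h1, name) == pytest.approx(getattr(h2, name), abs=1e-9)

    def test_pipeline_equals_straight_line_reimplementation(self, rng):
        # independent oracle: explicit loops, no shared code paths
        blocks = [8, 16, 24, 32]
        series = rng.standard_normal(64)
        h = hurst_family(series, block_sizes=blocks)
        log_s, log_rs, log_ers = [], [], []
        for size in blocks:
            rs_vals = []
            for start in range(0, (len(series) // size) * size, size):
                b = series[start : start + size]
                mean = sum(b) / size
                csum, mn, mx = 0.0, 0.0, 0.0
                for v in b:
                    csum += v - mean
                    mn, mx = min(mn, csum), max(mx, csum)
                sd = (sum((v - mean) ** 2 for v in b) / size) ** 0.5
                rs_vals.append((mx - mn) / sd)
            log_s.append(np.log10(size))
            log_rs.append(np.log10(sum(rs_vals) / len(rs_vals)))
            i = np.arange(1, size)
            ratio = (size - 0.5) / size * np.sum(np.sqrt((size - i) / i))
            from math import gamma, pi, sqrt

            ers = gamma((size - 1) / 2) * ratio / (gamma(size / 2) * sqrt(pi))
            log_ers.append(np.log10(ers))
        slope_emp = np.polyfit(log_s, log_rs, 1)[0]
        slope_th = np.polyfit(log_s, log_ers, 1)[0]
        assert h.h_empirical == pytest.approx(slope_emp, abs=1e-10)
        assert h.h_theoretical == pytest.approx(slope_th, abs=1e-10)
        assert h.h_corrected_empirical == pytest.approx(
            slope_emp - (slope_th - 0.5), abs=1e-10
        )

    def test_block_size_validation(self, rng):
        x = rng.standard_normal(1024)
        with pytest.raises(ValueError, match="at least 4 block sizes"):
            hurst_family(x, block_sizes=[8, 16, 32])
        with pytest.raises(ValueError, match="strictly increasing"):
            hurst_family(x, block_sizes=[8, 8, 16, 32])
        with pytest.raises(ValueError, match="256"):
            hurst_family(rng.standard_normal(100))


class TestDefaultBlocks:
    def test_blocks_are_divisors_within_bounds(self):
        opt_n, sizes = default_block_sizes(5000)
        assert 0.99 * 5000 <= opt_n <= 5000
        assert all(opt_n % s == 0 for s in sizes)
        assert sizes.min() >= 50 and sizes.max() <= opt_n // 2


class TestDfa:
    def test_white_noise_alpha_half(self):
        vals = [
            dfa_alpha(np.random.default_rng(s).standard_normal(4096))
            for s in range(20)
        ]
        assert np.mean(vals) == pytest.approx(0.5, abs=0.05)

    def test_integrated_noise_alpha_three_halves(self):
        vals = [
            dfa_alpha(np.cumsum(np.random.default_rng(s).standard_normal(4096)))
            for s in range(20)
        ]
        assert np.mean(vals) == pytest.approx(1.5, abs=0.1)

    def test_scale_invariant(self, rng):
        x = rng.standard_normal(1024)
        assert dfa_alpha(x) == pytest.approx(dfa_alpha(42.0 * x), abs=1e-10)

    def test_too_few_scales_rejected(self, rng):
        with pytest.raises(ValueError, match="4 scales"):
            dfa_alpha(make_series(rng.standard_normal(512)), scales=[8, 16, 32])
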