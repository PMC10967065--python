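"""Scale transforms, marginal moments, simulator, and the ITS design matrix."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from countcorr.core_model import (
    CountSeries,
    LatentParams,
    alpha_to_w_rho,
    alpha_to_w_variance,
    build_its_design,
    marginal_moments,
    simulate_counts,
    simulate_latent_ar1,
    simulate_series,
    w_to_alpha_rho,
)


class TestTransforms:
    @pytest.mark.parametrize(
        "s2, expected",
        [(0.0, 0.0), (0.5, math.exp(0.5) - 1), (1.0, math.exp(1.0) - 1)],
    )
    def test_variance_transform(self, s2, expected):
        assert alpha_to_w_variance(s2) == pytest.approx(expected, abs=1e-12)

    def test_variance_transform_rejects_negative(self):
        with pytest.raises(ValueError):
            alpha_to_w_variance(-0.1)

    @pytest.mark.parametrize(
        "rho_a, s2, expected",
        [
            (0.0, 0.5, 0.0),
            (1.0, 0.5, 1.0),
            (0.8, 0.5, (math.exp(0.4) - 1) / (math.exp(0.5) - 1)),
        ],
    )
    def test_rho_transform(self, rho_a, s2, expected):
        assert alpha_to_w_rho(rho_a, s2) == pytest.approx(expected, abs=1e-12)

    def test_rho_transform_monotone(self):
        vals = [alpha_to_w_rho(r, 0.5) for r in np.linspace(-1, 1, 41)]
        assert np.all(np.diff(vals) > 0)

    def test_rho_transform_degenerate_variance_returns_limit(self):
        assert alpha_to_w_rho(0.37, 0.0) == 0.37

    @pytest.mark.parametrize("rho_w, s2, expected", [(0.0, 0.5, 0.0), (1.0, 0.5, 1.0)])
    def test_inverse_rho_transform_fixed_points(self, rho_w, s2, expected):
        assert w_to_alpha_rho(rho_w, s2) == pytest.approx(expected, abs=1e-12)

    def test_inverse_rho_transform_example(self):
        assert w_to_alpha_rho(alpha_to_w_rho(0.8, 0.5), 0.5) == pytest.approx(0.8, abs=1e-12)

    def test_inverse_rejects_inadmissible(self):
        # more negative than any lognormal pair correlation
        with pytest.raises(ValueError):
            w_to_alpha_rho(-0.9, 2.0)

    @settings(derandomize=True, max_examples=200)
    @given(
        rho=st.floats(min_value=-0.99, max_value=1.0),
        s2=st.floats(min_value=1e-3, max_value=5.0),
    )
    def test_round_trip_identity(self, rho, s2):
        assert w_to_alpha_rho(alpha_to_w_rho(rho, s2), s2) == pytest.approx(rho, abs=1e-10)


class TestLatentSimulator:
    def test_degenerate_process_is_constant_zero(self):
        alpha = simulate_latent_ar1(5, LatentParams(0.0, 0.5), seed=1)
        np.testing.assert_array_equal(alpha, np.zeros(5))

    def test_iid_case_moments(self):
        params = LatentParams(0.5, 0.0)
        alpha = simulate_latent_ar1(100_000, params, seed=2)
        n = len(alpha)
        assert np.mean(alpha) == pytest.approx(-0.25, abs=3 * math.sqrt(0.5 / n))
        r1 = np.corrcoef(alpha[:-1], alpha[1:])[0, 1]
        assert r1 == pytest.approx(0.0, abs=3 / math.sqrt(n))

    def test_ar1_variance_and_lag2_autocorrelation(self):
        params = LatentParams(0.5, 0.8)
        alpha = simulate_latent_ar1(100_000, params, seed=3)
        n = len(alpha)
        # MC SE of the variance is inflated by autocorrelation; allow 4 nominal SEs
        assert np.var(alpha) == pytest.approx(0.5, abs=4 * 0.5 * math.sqrt(2 / n) * 3)
        r2 = np.corrcoef(alpha[:-2], alpha[2:])[0, 1]
        assert r2 == pytest.approx(0.64, abs=0.02)

    def test_reproducible_given_seed(self):
        a = simulate_latent_ar1(50, LatentParams(0.5, 0.8), seed=11)
        b = simulate_latent_ar1(50, LatentParams(0.5, 0.8), seed=11)
        np.testing.assert_array_equal(a, b)


class TestCountSimulator:
    def test_plain_poisson_moments(self):
        n = 100_000
        x = np.ones((n, 1))
        data = simulate_counts(x, [math.log(3)], np.zeros(n), seed=4)
        se = math.sqrt(3 / n)
        assert data.y.mean() == pytest.approx(3.0, abs=4 * se)
        assert data.y.var() == pytest.approx(3.0, abs=0.15)

    def test_marginal_variance_with_latent_noise(self):
        n = 200_000
        params = LatentParams(0.5, 0.8)
        x = np.ones((n, 1))
        data = simulate_series(x, [math.log(3)], params, seed=5)
        mu, var, rho1 = marginal_moments([1.0], [math.log(3)], params, h=1)
        assert var == pytest.approx(8.8385, abs=1e-3)  # mu + sigma2_w mu^2
        assert data.y.mean() == pytest.approx(mu, rel=0.02)
        assert data.y.var() == pytest.approx(var, rel=0.06)
        r1 = np.corrcoef(data.y[:-1], data.y[1:])[0, 1]
        assert r1 == pytest.approx(rho1, abs=0.02)

    def test_overflow_reports_time_index(self):
        x = np.ones((3, 1))
        with pytest.raises(OverflowError, match="t=1"):
            simulate_counts(x, [0.0], np.array([0.0, 800.0, 0.0]), seed=6)

    def test_degenerate_model_unit_mean(self):
        data = simulate_counts(np.ones((50_000, 1)), [0.0], np.zeros(50_000), seed=7)
        assert data.y.mean() == pytest.approx(1.0, abs=0.02)


class TestMarginalMoments:
    def test_no_latent_noise_is_equidispersed(self):
        mu, var, rho = marginal_moments([1.0], [math.log(3)], LatentParams(0.0, 0.5), h=1)
        assert mu == pytest.approx(3.0, abs=1e-12)
        assert var == pytest.approx(3.0, abs=1e-12)
        assert rho == 0.0

    def test_printed_formula_value(self):
        _, _, rho = marginal_moments([1.0], [math.log(3)], LatentParams(0.5, 0.8), h=1)
        # rho_w(1) / (1 + 1/(sigma2_w mu)) with mu = mu_{t+h} = 3
        sigma2_w = math.exp(0.5) - 1
        rho_w = (math.exp(0.4) - 1) / (math.exp(0.5) - 1)
        assert rho == pytest.approx(rho_w / (1 + 1 / (sigma2_w * 3)), abs=1e-12)
        assert rho == pytest.approx(0.5011, abs=5e-4)


class TestITSDesign:
    def test_small_design_rows(self):
        d = build_its_design(4, 2)
        expected = np.array(
            [[1, 1, 0, 0], [1, 2, 0, 0], [1, 3, 1, 1], [1, 4, 1, 2]], dtype=float
        )
        np.testing.assert_array_equal(d.matrix, expected)

    def test_minimal_design(self):
        d = build_its_design(2, 1)
        np.testing.assert_array_equal(d.matrix, [[1, 1, 0, 0], [1, 2, 1, 1]])

    @pytest.mark.parametrize("n, t0", [(10, 3), (25, 12), (100, 50)])
    def test_interaction_column_identity(self, n, t0):
        d = build_its_design(n, t0)
        t = np.arange(1, n + 1)
        np.testing.assert_allclose(d.matrix[:, 3], d.matrix[:, 2] * (t - t0))

    def test_t0_defaults_to_half(self):
        assert build_its_design(340).t0 == 170

    @pytest.mark.parametrize("t0", [0, 10, 11])
    def test_t0_out_of_range(self, t0):
        with pytest.raises(ValueError):
            build_its_design(10, t0)


class TestCountSeriesIO:
    def test_csv_round_trip(self, tmp_path):
        d = build_its_design(8, 4)
        data = simulate_series(d, (1.0, 0.01, 0.2, 0.0), LatentParams(0.5, 0.5), seed=9)
        path = tmp_path / "series.csv"
        data.to_csv(path)
        back = CountSeries.from_csv(path)
        np.testing.assert_array_equal(back.y, data.y)
        np.testing.assert_allclose(back.x, data.x)
        np.testing.assert_allclose(back.offset, data.offset)

    def test_rejects_negative_counts(self):
        with pytest.raises(ValueError):
            CountSeries(y=np.array([1, -2]), x=np.ones((2, 1)))
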