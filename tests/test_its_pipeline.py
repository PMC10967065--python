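"""Daily-count ITS design, synthetic generator, and excess-risk estimation."""

import math

import numpy as np
import pytest

from countcorr.glm_core import fit_poisson_glm, naive_covariance
from countcorr.its_pipeline import (
    DailyCovariates,
    build_rti_design,
    excess_risk_curve,
    synthesize_rti_data,
)
from countcorr.msrc import msrc_correct
from countcorr.splines import NaturalSpline
from countcorr.ub_correction import SandwichWorkspace, ub_correct


@pytest.fixture(scope="module")
def synth():
    cov, series, truth = synthesize_rti_data(n_days=1096, seed=21)
    return cov, series, truth


@pytest.fixture(scope="module")
def fitted(synth):
    cov, series, truth = synth
    design = build_rti_design(cov)
    fit = fit_poisson_glm(series)
    ws = SandwichWorkspace(fit)
    return design, fit, naive_covariance(fit), ub_correct(fit, workspace=ws), msrc_correct(fit, workspace=ws)


class TestNaturalSpline:
    def test_column_count_matches_df(self):
        x = np.linspace(0, 10, 200)
        for df in (1, 3, 5):
            assert NaturalSpline.fit(x, df).basis(x).shape == (200, df)

    def test_full_rank_with_intercept(self):
        x = np.linspace(0, 10, 200)
        B = np.column_stack([np.ones(200), NaturalSpline.fit(x, 5).basis(x)])
        assert np.linalg.matrix_rank(B) == 6

    def test_linear_tail_beyond_boundary(self):
        x = np.linspace(0, 1, 100)
        sp = NaturalSpline.fit(x, 4)
        # natural constraint: second differences vanish near the boundary tail
        xt = np.array([0.97, 0.98, 0.99, 1.0])
        b = sp.basis(xt)
        second_diff = b[2:] - 2 * b[1:-1] + b[:-2]
        np.testing.assert_allclose(second_diff, 0.0, atol=1e-4)

    def test_prediction_consistent_with_fit(self):
        x = np.linspace(0, 10, 50)
        sp = NaturalSpline.fit(x, 3)
        np.testing.assert_allclose(sp.basis(x[10:13]), sp.basis(x)[10:13], atol=1e-12)


class TestDesign:
    def test_column_structure(self, synth):
        cov, _, _ = synth
        design = build_rti_design(cov, k=2, temp_df=3, int_df=5)
        # 1 + 4 harmonics + 6 dow + 2 holiday + 2 precip + 3 temp + t + X + 5 interaction
        assert design.x.shape[1] == 25
        assert sum(c.startswith("sin") or c.startswith("cos") for c in design.columns) == 4
        assert np.linalg.matrix_rank(design.x) == 25

    def test_harmonics_periodic(self, synth):
        cov, _, _ = synth
        design = build_rti_design(cov)
        t = design.t_index
        T = 365.25
        for name, fn in (("sin1", np.sin), ("cos2", np.cos)):
            j = design.columns.index(name)
            theta = int(name[-1])
            np.testing.assert_allclose(
                design.x[:, j], fn(2 * theta * np.pi * t / T), atol=1e-12
            )
        # the harmonic columns are T-periodic in t (4T is a whole number of days)
        col = np.sin(2 * np.pi * np.arange(1, 2000) / T)
        assert col[10 + 1461 - 1] == pytest.approx(col[10 - 1], abs=1e-9)

    def test_interaction_zero_before_intervention(self, synth):
        cov, _, truth = synth
        design = build_rti_design(cov)
        pre = np.asarray(cov.intervention) == 0
        np.testing.assert_array_equal(design.x[np.ix_(pre, design.interaction_cols)], 0.0)
        assert design.x[pre, design.intervention_col].max() == 0.0

    def test_unseen_category_level_rejected(self, synth):
        cov, _, _ = synth
        bad = DailyCovariates(
            date=cov.date,
            pop_car_product=cov.pop_car_product,
            dow=cov.dow,
            holiday=np.where(np.arange(cov.n) == 5, 9, cov.holiday),
            precip_mm_h=cov.precip_mm_h,
            temp=cov.temp,
            intervention=cov.intervention,
        )
        with pytest.raises(ValueError, match="unseen"):
            build_rti_design(bad)

    def test_nonpositive_exposure_rejected(self, synth):
        cov, _, _ = synth
        with pytest.raises(ValueError, match="exposure"):
            DailyCovariates(
                date=cov.date,
                pop_car_product=np.zeros(cov.n),
                dow=cov.dow,
                holiday=cov.holiday,
                precip_mm_h=cov.precip_mm_h,
                temp=cov.temp,
                intervention=cov.intervention,
            )

    def test_precip_categories_from_cutoffs(self, synth):
        cov, _, _ = synth
        cat = cov.precip_cat
        assert set(np.unique(cat)) <= {0, 1, 2}
        assert np.all(cat[cov.precip_mm_h == 0] == 0)
        assert np.all(cat[cov.precip_mm_h > 2.5] == 2)


class TestSyntheticGenerator:
    def test_no_latent_noise_leaves_no_residual_autocorrelation(self):
        from statsmodels.tsa.stattools import pacf

        cov, series, _ = synthesize_rti_data(n_days=1096, seed=31, sigma2_alpha=0.0, rho_alpha=0.0)
        fit = fit_poisson_glm(series)
        resid = (series.y - fit.mu_hat) / np.sqrt(fit.mu_hat)
        vals = pacf(resid, nlags=5)[1:]
        assert np.max(np.abs(vals)) < 4 / math.sqrt(series.n)

    def test_generator_reproducible(self):
        _, s1, _ = synthesize_rti_data(n_days=800, seed=5)
        _, s2, _ = synthesize_rti_data(n_days=800, seed=5)
        np.testing.assert_array_equal(s1.y, s2.y)

    def test_full_study_length_runs_end_to_end(self):
        cov, series, truth = synthesize_rti_data(n_days=2557, seed=8)
        fit = fit_poisson_glm(series)
        corr = msrc_correct(fit)
        assert corr.G.shape == (series.p, series.p)

    def test_rejects_short_series(self):
        with pytest.raises(ValueError):
            synthesize_rti_data(n_days=400, seed=1)


class TestExcessRisk:
    def test_null_effect_gives_zero_er(self, fitted):
        design, fit, naive, *_ = fitted
        import copy

        f = copy.deepcopy(fit)
        idx = [design.intervention_col] + design.interaction_cols
        f.beta_hat[idx] = 0.0
        curve = excess_risk_curve(f, naive, design, [500.0, 900.0])
        np.testing.assert_allclose(curve.er_pct, 0.0, atol=1e-12)
        # symmetric on the log scale around 0
        np.testing.assert_allclose(
            (1 + curve.ci_lo / 100) * (1 + curve.ci_hi / 100), 1.0, atol=1e-10
        )

    def test_zero_covariance_degenerates_to_point(self, fitted):
        design, fit, naive, *_ = fitted
        curve = excess_risk_curve(fit, np.zeros_like(naive), design, [700.0])
        assert curve.ci_lo[0] == pytest.approx(curve.er_pct[0])
        assert curve.ci_hi[0] == pytest.approx(curve.er_pct[0])

    def test_delta_ci_matches_parametric_bootstrap(self, rng):
        """The lognormal CI from the printed SE formula agrees with the
        quantiles of 1e5 draws of the estimated linear combination."""
        eta, se = math.log(0.6), 0.13
        draws = (np.exp(rng.normal(eta, se, 100_000)) - 1) * 100
        lo, hi = np.percentile(draws, [2.5, 97.5])
        ci_lo = (math.exp(eta - 1.959964 * se) - 1) * 100
        ci_hi = (math.exp(eta + 1.959964 * se) - 1) * 100
        assert ci_lo == pytest.approx(lo, abs=0.5)
        assert ci_hi == pytest.approx(hi, abs=0.5)
        assert (math.exp(eta) - 1) * 100 == pytest.approx(-40.0, abs=1e-9)

    def test_out_of_range_times_rejected(self, fitted):
        design, fit, naive, *_ = fitted
        with pytest.raises(ValueError, match="outside"):
            excess_risk_curve(fit, naive, design, [design.n + 100.0])

    def test_point_estimates_identical_interval_widths_ordered(self, fitted):
        design, fit, naive, ub, ms = fitted
        times = np.array([400.0, 700.0, 1000.0])
        c_naive = excess_risk_curve(fit, naive, design, times)
        c_ub = excess_risk_curve(fit, ub, design, times)
        c_ms = excess_risk_curve(fit, ms, design, times)
        np.testing.assert_allclose(c_naive.er_pct, c_ub.er_pct, atol=1e-12)
        np.testing.assert_allclose(c_ub.er_pct, c_ms.er_pct, atol=1e-12)
        w_naive = c_naive.ci_hi - c_naive.ci_lo
        w_ub = c_ub.ci_hi - c_ub.ci_lo
        w_ms = c_ms.ci_hi - c_ms.ci_lo
        if 0 <= ub.rho1_used <= ms.rho1_used:
            assert np.all(w_naive <= w_ub + 1e-9)
            assert np.all(w_ub <= w_ms + 1e-9)
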