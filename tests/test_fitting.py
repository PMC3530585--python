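"""OLS on the logit scale, AIC, stepwise selection and diagnostics."""

import itertools
import math

import numpy as np
import pytest

import budfate as bf
from budfate.exceptions import SingularDesignError, UndefinedRSquaredError
from budfate.fitting import gaussian_aic
from budfate.model import ModelParameters, TERMS


def surface_records(params, lw1, pi):
    """Records lying exactly on the model surface (no noise)."""
    return [
        bf.TreeYearRecord(
            tree_id=i + 1, year=1, lw1=l, pi=p, pls=bf.predict_pls(params, l, p)
        )
        for i, (l, p) in enumerate(zip(lw1, pi))
    ]


def normal_equations(X, y):
    """Independent oracle: solve X'X beta = X'y directly."""
    return np.linalg.solve(X.T @ X, X.T @ y)


class TestFitModel:
    def test_exact_interpolation_recovers_truth(self):
        truth = ModelParameters(log_a=1.2, c=6e-3, e=-1.4e-2)
        recs = surface_records(truth, [120, 220, 320, 180], [0.1, 0.4, 0.7, 0.55])
        fit = bf.fit_model(recs, ("LW1", "PIxLW1"))
        assert fit.params.log_a == pytest.approx(truth.log_a, abs=1e-10)
        assert fit.params.c == pytest.approx(truth.c, abs=1e-10)
        assert fit.params.e == pytest.approx(truth.e, abs=1e-10)
        assert fit.rss == pytest.approx(0.0, abs=1e-18)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            n = rng.integers(10, 60)
            lw1 = rng.uniform(50, 400, n)
            pi = rng.uniform(0, 0.9, n)
            pls = rng.uniform(0.02, 0.98, n)
            recs = [
                bf.TreeYearRecord(i + 1, 1, lw1[i], pi[i], pls[i]) for i in range(n)
            ]
            fit = bf.fit_model(recs, TERMS)
            X, y = bf.logit_linearize(recs, TERMS)
            beta = normal_equations(X, y)
            got = [fit.params.log_a, fit.params.b, fit.params.c, fit.params.e]
            np.testing.assert_allclose(got, beta, atol=1e-8)

    def test_two_duplicated_points_interpolate_one_term(self):
        truth = ModelParameters(log_a=0.5, c=4e-3)
        base = surface_records(truth, [100, 300], [0.0, 0.0])
        recs = base * 10
        fit = bf.fit_model(recs, ("LW1",))
        assert fit.params.log_a == pytest.approx(0.5, abs=1e-10)
        assert fit.params.c == pytest.approx(4e-3, abs=1e-12)
        assert fit.rss == pytest.approx(0.0, abs=1e-18)

    def test_constant_columns_raise_singular_design(self):
        recs = surface_records(ModelParameters(log_a=0.3), [150] * 10, [0.4] * 10)
        with pytest.raises(SingularDesignError):
            bf.fit_model(recs, ("LW1",))

    def test_needs_more_rows_than_coefficients(self):
        recs = surface_records(ModelParameters(log_a=0.3), [100, 200], [0.1, 0.5])
        with pytest.raises(SingularDesignError):
            bf.fit_model(recs, ("LW1", "PIxLW1"))


class TestAic:
    def test_penalty_monotone_in_parameter_count(self):
        assert gaussian_aic(40, 5.0, 2) < gaussian_aic(40, 5.0, 3)

    def test_halved_rss_drops_by_n_log_two(self):
        assert gaussian_aic(40, 4.0, 3) - gaussian_aic(40, 8.0, 3) == pytest.approx(
            -40 * math.log(2)
        )

    def test_perfect_fit_sentinel(self):
        with pytest.warns(UserWarning, match="perfect fit"):
            assert gaussian_aic(10, 0.0, 2) == -math.inf

    def test_matches_profile_likelihood_oracle(self):
        """Our convention differs from -2*loglik + 2k by a constant in n only."""
        n, rng = 25, np.random.default_rng(3)
        y = rng.normal(size=n)
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        beta = normal_equations(X, y)
        rss = float(((y - X @ beta) ** 2).sum())
        sigma2 = rss / n  # profile MLE of the error variance
        loglik = -0.5 * n * (math.log(2 * math.pi) + math.log(sigma2) + 1)
        full_aic = -2 * loglik + 2 * (X.shape[1] + 1)
        constant = n * (math.log(2 * math.pi) + 1)
        assert gaussian_aic(n, rss, X.shape[1]) == pytest.approx(full_aic - constant)


def exhaustive_aic_minimum(records):
    """Oracle: AIC over all 8 term subsets."""
    best = None
    for k in range(4):
        for terms in itertools.combinations(TERMS, k):
            fit = bf.fit_model(records, terms)
            if best is None or fit.aic < best.aic:
                best = fit
    return best


class TestStepwise:
    def test_study_data_selects_lw1_and_interaction(self, corrected_records):
        result = bf.stepwise_backward_aic(corrected_records)
        assert set(result.fit.terms) == {"LW1", "PIxLW1"}
        assert result.trace[0]["dropped"] == "PI"
        assert result.trace[-1]["dropped"] is None

    def test_equals_exhaustive_minimum_on_study_data(self, corrected_records):
        best = exhaustive_aic_minimum(corrected_records)
        got = bf.stepwise_backward_aic(corrected_records).fit
        assert got.terms == best.terms
        assert got.aic == pytest.approx(best.aic)

    def test_equals_exhaustive_minimum_on_synthetic_draws(self):
        truth = bf.REFERENCE_PARAMS
        for seed in range(5):
            data = bf.generate(
                bf.SyntheticConfig(
                    true_params=truth,
                    n_records=60,
                    noise=bf.LogitNormalNoise(0.4),
                    seed=seed,
                )
            )
            got = bf.stepwise_backward_aic(data).fit
            best = exhaustive_aic_minimum(data)
            assert got.aic <= best.aic + 1e-9

    def test_pure_lw1_effect_is_recovered(self):
        truth = ModelParameters(log_a=1.0, c=8e-3)
        data = bf.generate(
            bf.SyntheticConfig(
                true_params=truth,
                n_records=1000,
                noise=bf.LogitNormalNoise(0.1),
                seed=11,
            )
        )
        assert bf.stepwise_backward_aic(data).fit.terms == ("LW1",)


class TestRSquared:
    def test_perfect_fit_is_one(self):
        truth = ModelParameters(log_a=1.0, c=6e-3)
        recs = surface_records(truth, [100, 200, 300, 150], [0.2, 0.3, 0.1, 0.6])
        assert bf.r_squared(bf.fit_model(recs, ("LW1",))) == pytest.approx(1.0)

    def test_intercept_only_is_zero(self, corrected_records):
        assert bf.r_squared(bf.fit_model(corrected_records, ())) == pytest.approx(
            0.0, abs=1e-12
        )

    def test_undefined_for_constant_response(self):
        truth = ModelParameters(log_a=0.7)
        recs = surface_records(truth, [100, 200, 300], [0.2, 0.5, 0.8])
        fit = bf.fit_model(recs, ("LW1",))
        with pytest.raises(UndefinedRSquaredError):
            bf.r_squared(fit)

    def test_pls_scale_value_reported_alongside(self, selected_fit):
        logit_r2 = bf.r_squared(selected_fit)
        pls_r2 = bf.pls_scale_r_squared(selected_fit)
        assert 0 < logit_r2 < 1 and 0 < pls_r2 < 1


class TestDiagnostics:
    @staticmethod
    def _fit_with_noise(noise, seed=5, n=200):
        rng = np.random.default_rng(seed)
        lw1 = rng.uniform(100, 360, n)
        pi = rng.uniform(0, 0.8, n)
        truth = bf.REFERENCE_PARAMS
        eta = truth.log_a + truth.c * lw1 + truth.e * pi * lw1
        y = eta + noise(rng, eta)
        pls = 1 / (1 + np.exp(y))
        recs = [bf.TreeYearRecord(i + 1, 1, lw1[i], pi[i], pls[i]) for i in range(n)]
        return bf.fit_model(recs, ("LW1", "PIxLW1"))

    def test_well_specified_residuals_pass(self):
        fit = self._fit_with_noise(lambda rng, eta: rng.normal(0, 0.3, eta.size))
        report = bf.residual_diagnostics(fit)
        assert report.normality_ok and report.homoscedasticity_ok

    def test_variance_growing_with_fit_is_flagged(self):
        fit = self._fit_with_noise(
            lambda rng, eta: rng.normal(0, 0.25 * np.abs(eta), eta.size)
        )
        assert not bf.residual_diagnostics(fit).homoscedasticity_ok

    def test_study_data_report_completes(self, selected_fit):
        report = bf.residual_diagnostics(selected_fit)
        assert 0 <= report.normality_pvalue <= 1
        assert 0 <= report.heteroscedasticity_pvalue <= 1

    def test_requires_enough_residuals(self):
        truth = ModelParameters(log_a=1.0, c=6e-3)
        recs = surface_records(truth, [100, 200, 300, 150], [0.2, 0.3, 0.1, 0.6])
        with pytest.raises(ValueError):
            bf.residual_diagnostics(bf.fit_model(recs, ("LW1",)))


def test_aic_ordering_invariant_to_response_shift(corrected_records):
    """Adding a constant to the logit response leaves AIC differences intact."""
    shifted = [
        bf.TreeYearRecord(
            r.tree_id, r.year, r.lw1, r.pi,
            1.0 / (1.0 + math.exp(math.log((1 - r.pls) / r.pls) + 0.5)),
        )
        for r in corrected_records
    ]
    for records in (corrected_records, shifted):
        fits = {t: bf.fit_model(records, t).aic for t in [("LW1",), ("LW1", "PIxLW1"), TERMS]}
    base = {t: bf.fit_model(corrected_records, t).aic for t in fits}
    diffs_base = [base[t] - base[("LW1",)] for t in fits]
    diffs_shift = [fits[t] - fits[("LW1",)] for t in fits]
    np.testing.assert_allclose(diffs_base, diffs_shift, atol=1e-9)
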