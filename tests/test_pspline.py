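"""Basis construction and the penalized Poisson smoother.

The independent oracles are unpenalized Poisson GLM fits (statsmodels):
at lambda = 0 the P-spline must reproduce the saturated-basis GLM, and at
lambda -> infinity with a second-order penalty it must collapse onto the
log-linear (Gompertz) GLM.
"""

import warnings

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

import deplife as dl


def _expected_counts(rate_fn, exposure=1000.0, ages=None):
    """Deterministic counts table: d = e * rate(age) (no sampling noise)."""
    ages = np.arange(18, 101) if ages is None else ages
    e = np.full(len(ages), float(exposure))
    return pd.DataFrame({"age": ages, "deaths": e * rate_fn(ages), "exposure": e})


def _gompertz(ages, a=3e-5, b=0.1):
    return a * np.exp(b * np.asarray(ages, dtype=float))


class TestBasis:
    def test_partition_of_unity_and_bandedness(self, basis):
        np.testing.assert_allclose(basis.B.sum(axis=1), 1.0, atol=1e-12)
        assert ((basis.B != 0).sum(axis=1) <= basis.degree + 1).all()

    def test_default_shape_is_83_by_24(self, basis):
        assert basis.B.shape == (83, 24)
        assert basis.n_basis == basis.n_segments + basis.degree

    def test_degree_zero_is_indicator_basis(self):
        b = dl.build_basis(age_min=0, age_max=8, n_segments=4, degree=0, penalty_order=1)
        assert set(np.unique(b.B)) <= {0.0, 1.0}
        assert (b.B.sum(axis=1) == 1).all()

    def test_invalid_age_range_rejected(self):
        with pytest.raises(ValueError):
            dl.build_basis(age_min=50, age_max=50)

    def test_penalty_matrix_kills_polynomials_up_to_order(self, basis):
        i = np.arange(basis.n_basis, dtype=float)
        np.testing.assert_allclose(basis.D @ np.ones_like(i), 0.0, atol=1e-12)
        np.testing.assert_allclose(basis.D @ i, 0.0, atol=1e-12)
        assert np.abs(basis.D @ i**2).max() > 0


class TestFitPspline:
    @pytest.mark.parametrize("lam", [0.0, 10.0, 1e6])
    def test_constant_rate_fits_pooled_rate_at_any_lambda(self, basis, lam):
        counts = _expected_counts(lambda a: np.full(len(a), 0.02))
        fit = dl.fit_pspline(counts, basis, lam)
        rates = dl.predict_rates(fit, basis)["rate"]
        np.testing.assert_allclose(rates, 0.02, rtol=1e-6)

    def test_lambda_zero_matches_unpenalized_glm(self, basis, sim50k):
        _, _, counts = sim50k
        sl = dl.counts_slice(counts, "male", dl.ALL)
        fit = dl.fit_pspline(sl, basis, 0.0)
        keep = sl[sl["exposure"] > 0]
        B = basis.B[np.searchsorted(basis.ages, keep["age"].to_numpy())]
        glm = sm.GLM(
            keep["deaths"].to_numpy(),
            B,
            family=sm.families.Poisson(),
            offset=np.log(keep["exposure"].to_numpy()),
        ).fit()
        np.testing.assert_allclose(fit.fitted_deaths, glm.fittedvalues, rtol=1e-6)

    def test_huge_lambda_matches_gompertz_glm_slope(self, basis, sim50k):
        _, _, counts = sim50k
        sl = dl.counts_slice(counts, "male", dl.ALL)
        fit = dl.fit_pspline(sl, basis, 1e8)
        keep = sl[sl["exposure"] > 0]
        X = np.column_stack([np.ones(len(keep)), keep["age"].to_numpy(dtype=float)])
        glm = sm.GLM(
            keep["deaths"].to_numpy(),
            X,
            family=sm.families.Poisson(),
            offset=np.log(keep["exposure"].to_numpy()),
        ).fit()
        eta = basis.B @ fit.coefficients
        slope = np.polyfit(basis.ages.astype(float), eta, 1)[0]
        assert slope == pytest.approx(glm.params[1], abs=1e-4)
        assert fit.effective_dimension == pytest.approx(2.0, abs=0.05)

    @pytest.mark.parametrize("quintile", [dl.ALL, 1, 5])
    @pytest.mark.parametrize("sex", dl.SEXES)
    def test_death_count_conservation(self, basis, sim50k, sex, quintile):
        _, _, counts = sim50k
        sl = dl.counts_slice(counts, sex, quintile)
        observed = sl.loc[sl["exposure"] > 0, "deaths"].sum()
        for lam in [0.0, 1.0, 1e2, 1e4, 1e6, 1e8]:
            fit = dl.fit_pspline(sl, basis, lam)
            assert fit.fitted_deaths.sum() == pytest.approx(observed, rel=1e-6)

    def test_effective_dimension_monotone_in_lambda(self, basis, sim50k):
        _, _, counts = sim50k
        sl = dl.counts_slice(counts, "female", dl.ALL)
        eds = [
            dl.fit_pspline(sl, basis, lam).effective_dimension
            for lam in dl.DEFAULT_LAMBDA_GRID[::4]
        ]
        assert all(e2 <= e1 + 1e-8 for e1, e2 in zip(eds, eds[1:]))
        assert all(1.0 - 1e-8 <= e <= basis.n_basis + 1e-8 for e in eds)

    def test_covariance_symmetric_psd(self, basis, sim50k):
        _, _, counts = sim50k
        fit = dl.fit_pspline(dl.counts_slice(counts, "male", 3), basis, 100.0)
        cov = fit.covariance
        np.testing.assert_allclose(cov, cov.T, atol=1e-12)
        assert np.linalg.eigvalsh(cov).min() > -1e-12

    def test_zero_exposure_cells_excluded_with_warning(self, basis):
        counts = _expected_counts(_gompertz)
        counts.loc[counts["age"] >= 99, "exposure"] = 0.0
        counts.loc[counts["age"] >= 99, "deaths"] = 0.0
        with pytest.warns(UserWarning, match="zero-exposure"):
            fit = dl.fit_pspline(counts, basis, 10.0)
        assert fit.converged
        assert len(fit.ages_used) == 81
        assert len(dl.predict_rates(fit, basis)) == 83  # prediction on full grid

    def test_all_zero_deaths_is_degenerate_not_an_error(self, basis):
        counts = _expected_counts(lambda a: np.zeros(len(a)))
        fit = dl.fit_pspline(counts, basis, 10.0)
        assert fit.degenerate and not fit.converged
        with pytest.raises(ValueError):
            dl.predict_rates(fit, basis)

    def test_weight_scaling_absorbed_exactly_at_lambda_zero(self, basis, sim50k):
        _, _, counts = sim50k
        sl = dl.counts_slice(counts, "male", dl.ALL)
        scaled = sl.assign(deaths=3.0 * sl["deaths"], exposure=3.0 * sl["exposure"])
        r1 = dl.predict_rates(dl.fit_pspline(sl, basis, 0.0), basis)["rate"]
        r2 = dl.predict_rates(dl.fit_pspline(scaled, basis, 0.0), basis)["rate"]
        np.testing.assert_allclose(r1, r2, rtol=1e-6)

    def test_weight_scaling_matched_by_lambda_scaling(self, basis, sim50k):
        """Scaling (d, e) by k with lambda -> k*lambda is the same fit.

        The Poisson log-likelihood scales by k under a joint count scaling,
        so the penalized maximizer is invariant when the penalty scales
        along; the nominal CIs, however, shrink by sqrt(k) — weighted
        counts are treated as Poisson, so uniform weight inflation claims
        information the sample does not have.
        """
        _, _, counts = sim50k
        sl = dl.counts_slice(counts, "male", dl.ALL)
        scaled = sl.assign(deaths=3.0 * sl["deaths"], exposure=3.0 * sl["exposure"])
        r1 = dl.predict_rates(dl.fit_pspline(sl, basis, 100.0), basis)
        r2 = dl.predict_rates(dl.fit_pspline(scaled, basis, 300.0), basis)
        np.testing.assert_allclose(r1["rate"], r2["rate"], rtol=1e-7)
        np.testing.assert_allclose(
            r2["log_rate_se"], r1["log_rate_se"] / np.sqrt(3.0), rtol=1e-6
        )


class TestSelectLambda:
    def test_single_point_grid_returns_that_fit(self, basis, sim50k):
        _, _, counts = sim50k
        sl = dl.counts_slice(counts, "male", 2)
        fit = dl.select_lambda(sl, basis, grid=[42.0])
        assert fit.lam == 42.0

    def test_empty_grid_rejected(self, basis, sim50k):
        _, _, counts = sim50k
        with pytest.raises(ValueError):
            dl.select_lambda(dl.counts_slice(counts, "male", 2), basis, grid=[])

    def test_gompertz_data_selects_low_effective_dimension(self, basis):
        counts = _expected_counts(_gompertz, exposure=50_000.0)
        fit = dl.select_lambda(counts, basis)
        assert fit.effective_dimension <= 4.0

    def test_bump_in_hazard_beats_the_gompertz_limit(self, basis):
        def bumpy(ages):
            ages = np.asarray(ages, dtype=float)
            return _gompertz(ages) * np.exp(0.8 * np.exp(-0.5 * ((ages - 40) / 4.0) ** 2))

        counts = _expected_counts(bumpy, exposure=50_000.0)
        best = dl.select_lambda(counts, basis)
        gompertz_limit = dl.fit_pspline(counts, basis, 1e8)
        assert best.bic < gompertz_limit.bic
        assert best.effective_dimension > gompertz_limit.effective_dimension

    def test_bic_ties_break_toward_smoother_fit(self, basis):
        counts = _expected_counts(_gompertz, exposure=50_000.0)
        f1 = dl.fit_pspline(counts, basis, 1e6)
        # a duplicated grid point is a guaranteed tie
        best = dl.select_lambda(counts, basis, grid=[1e6, 1e6])
        assert best.lam == f1.lam


class TestPredictRates:
    def test_rate_is_exp_of_linear_predictor(self, basis, sim50k):
        _, _, counts = sim50k
        fit = dl.fit_pspline(dl.counts_slice(counts, "female", 1), basis, 100.0)
        rc = dl.predict_rates(fit, basis)
        np.testing.assert_allclose(
            rc["rate"], np.exp(basis.B @ fit.coefficients), rtol=1e-12
        )
        assert (rc["ci_low"] <= rc["rate"]).all() and (rc["rate"] <= rc["ci_high"]).all()
        assert (rc["ci_low"] > 0).all()

    def test_ci_width_shrinks_with_more_data(self, basis, sim50k):
        _, _, counts = sim50k
        sl = dl.counts_slice(counts, "male", 4)
        big = sl.assign(deaths=100.0 * sl["deaths"], exposure=100.0 * sl["exposure"])
        se_small = dl.predict_rates(dl.fit_pspline(sl, basis, 100.0), basis)["log_rate_se"]
        se_big = dl.predict_rates(dl.fit_pspline(big, basis, 100.0), basis)["log_rate_se"]
        assert se_big.mean() < 0.2 * se_small.mean()

    def test_constant_fit_has_constant_band(self, basis):
        counts = _expected_counts(lambda a: np.full(len(a), 0.05))
        rc = dl.predict_rates(dl.fit_pspline(counts, basis, 1e6), basis)
        assert rc["rate"].std() < 1e-6
        assert (rc["ci_low"] < rc["rate"]).all() and (rc["rate"] < rc["ci_high"]).all()
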