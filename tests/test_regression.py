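"""Curve estimation and multiple OLS: statistics block and identities."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gourava_qspr.regression import (
    CURVE_FORMS,
    DegreesOfFreedomError,
    DomainError,
    RankError,
    f_pvalue,
    fit_curve,
    fit_multiple,
    format_p,
)

RNG = np.random.default_rng(20240901)


def random_xy(n=13, seed=0):
    rng = np.random.default_rng(seed)
    x = rng.uniform(20, 300, size=n)
    y = 50 + 0.4 * x + rng.normal(0, 10, size=n)
    return x, np.abs(y) + 1.0  # positive, so every form is admissible


def assert_identities(fit, atol=1e-10):
    assert fit.r == pytest.approx(math.sqrt(fit.r2), abs=atol)
    assert fit.adj_r2 == pytest.approx(
        1 - (1 - fit.r2) * (fit.n - 1) / (fit.n - fit.k - 1), abs=atol
    )
    if fit.r2 < 1:
        expected_f = (fit.r2 / fit.k) / ((1 - fit.r2) / (fit.n - fit.k - 1))
        assert fit.f == pytest.approx(expected_f, rel=1e-10)


def test_exact_linear_fit_has_unit_r_and_zero_see():
    x = np.arange(1.0, 14.0)
    fit = fit_curve(x, 2 * x + 1, "linear")
    assert fit.intercept == pytest.approx(1.0, abs=1e-10)
    assert fit.coefficients[0] == pytest.approx(2.0, abs=1e-12)
    assert fit.r == 1.0
    assert fit.see == pytest.approx(0.0, abs=1e-10)
    assert fit.p == 0.0


@pytest.mark.parametrize("form", CURVE_FORMS)
@pytest.mark.parametrize("seed", [1, 2, 3])
def test_statistic_identities_hold(form, seed):
    x, y = random_xy(seed=seed)
    fit = fit_curve(x, y, form)
    assert_identities(fit)
    assert 0.0 <= fit.r2 <= 1.0
    assert fit.adj_r2 <= fit.r2


@pytest.mark.parametrize("seed", [1, 2, 3, 4])
def test_nested_polynomial_r2_monotone(seed):
    x, y = random_xy(seed=seed)
    r2 = [fit_curve(x, y, f).r2 for f in ("linear", "quadratic", "cubic")]
    assert r2[0] <= r2[1] + 1e-12 and r2[1] <= r2[2] + 1e-12


@pytest.mark.parametrize("form", ["linear", "quadratic", "cubic", "logarithmic"])
def test_coefficients_match_normal_equations(form, normal_equations):
    x, y = random_xy(seed=7)
    fit = fit_curve(x, y, form)
    if form == "logarithmic":
        X = np.column_stack([np.ones_like(x), np.log(x)])
    else:
        k = {"linear": 1, "quadratic": 2, "cubic": 3}[form]
        X = np.column_stack([x ** j for j in range(k + 1)])
    expected = normal_equations(X, y)
    assert np.allclose([fit.intercept, *fit.coefficients], expected, atol=1e-8, rtol=1e-8)


def test_statistics_match_statsmodels_oracle():
    import statsmodels.api as sm

    x, y = random_xy(seed=11)
    fit = fit_curve(x, y, "linear")
    sm_fit = sm.OLS(y, sm.add_constant(x)).fit()
    assert fit.r2 == pytest.approx(sm_fit.rsquared, abs=1e-12)
    assert fit.adj_r2 == pytest.approx(sm_fit.rsquared_adj, abs=1e-12)
    assert fit.f == pytest.approx(sm_fit.fvalue, rel=1e-10)
    assert fit.p == pytest.approx(sm_fit.f_pvalue, abs=1e-12)
    assert fit.see == pytest.approx(math.sqrt(sm_fit.mse_resid), abs=1e-12)

    X = np.column_stack([x, np.log(x), x ** 2])
    fitm = fit_multiple(X, y)
    smm = sm.OLS(y, sm.add_constant(X)).fit()
    assert fitm.r2 == pytest.approx(smm.rsquared, abs=1e-10)
    assert np.allclose([fitm.intercept, *fitm.coefficients], smm.params, atol=1e-8)


@settings(max_examples=30, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10_000))
def test_permutation_invariance(seed):
    x, y = random_xy(seed=seed)
    rng = np.random.default_rng(seed + 1)
    perm = rng.permutation(len(x))
    a, b = fit_curve(x, y, "quadratic"), fit_curve(x[perm], y[perm], "quadratic")
    for attr in ("r", "r2", "adj_r2", "see", "f", "p"):
        assert getattr(a, attr) == pytest.approx(getattr(b, attr), rel=1e-9, abs=1e-12)


class TestExponentialForm:
    def test_fits_on_log_scale(self):
        x = np.linspace(1, 10, 12)
        y = 3.5 * np.exp(0.25 * x)
        fit = fit_curve(x, y, "exponential")
        assert fit.response_scale == "log"
        assert fit.intercept == pytest.approx(3.5, rel=1e-9)  # reported as a, not ln a
        assert fit.coefficients[0] == pytest.approx(0.25, abs=1e-12)
        assert fit.r == 1.0 and fit.see == pytest.approx(0.0, abs=1e-9)

    def test_see_is_log_scale_residual(self):
        rng = np.random.default_rng(3)
        x = np.linspace(1, 10, 40)
        y = 2.0 * np.exp(0.1 * x) * np.exp(rng.normal(0, 0.2, size=40))
        fit = fit_curve(x, y, "exponential")
        assert 0.1 < fit.see < 0.4  # sd of the log-residual, not of y

    def test_rejects_nonpositive_response(self):
        with pytest.raises(DomainError, match="y > 0"):
            fit_curve([1, 2, 3, 4], [1.0, -1.0, 2.0, 3.0], "exponential")


def test_logarithmic_rejects_nonpositive_predictor():
    with pytest.raises(DomainError, match="x > 0"):
        fit_curve([0.0, 1, 2, 3], [1.0, 2, 3, 4], "logarithmic")


def test_insufficient_observations_raise():
    with pytest.raises(DegreesOfFreedomError):
        fit_curve([1.0, 2.0], [1.0, 2.0], "linear")
    with pytest.raises(DegreesOfFreedomError):
        fit_curve([1, 2, 3, 4], [1, 2, 3, 4], "cubic")


def test_collinear_design_names_offending_column():
    x = np.full(13, 5.0)  # constant predictor duplicates the intercept
    with pytest.raises(RankError, match="x\\^1"):
        fit_curve(x, np.arange(13.0), "linear")


def test_f_pvalue_boundaries_and_identity():
    from scipy import stats

    assert f_pvalue(0.0, 1, 13) == pytest.approx(1.0)
    assert f_pvalue(31.246, 1, 13) < 0.001
    f = 2.7
    assert f_pvalue(f, 1, 13) + stats.f.cdf(f, 1, 11) == pytest.approx(1.0)
    with pytest.raises(DegreesOfFreedomError):
        f_pvalue(1.0, 5, 6)


def test_format_p():
    assert format_p(0.0004) == "<0.001"
    assert format_p(0.045) == "0.045"


class TestMultiple:
    def test_exact_single_predictor_dependence(self, printed_indices, properties):
        X = printed_indices.to_numpy(dtype=float)
        y = 2.0 + 0.5 * X[:, 0]  # depends on the first index column only
        fit = fit_multiple(X, y)
        assert fit.r == pytest.approx(1.0)
        assert np.allclose(fit.predict(X), y, atol=1e-8)

    def test_dof_error_when_n_too_small(self):
        X = np.arange(72, dtype=float).reshape(9, 8)
        with pytest.raises(DegreesOfFreedomError):
            fit_multiple(X, np.arange(9.0))

    def test_degenerate_response_flagged(self):
        X = RNG.uniform(size=(13, 2))
        fit = fit_multiple(X, np.zeros(13))
        assert fit.degenerate and fit.r == 0.0

    def test_condition_number_recorded(self, printed_indices, properties):
        fit = fit_multiple(printed_indices.to_numpy(float), properties["Da"].to_numpy())
        assert fit.condition_number is not None and fit.condition_number > 1e3
        assert_identities(fit)
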