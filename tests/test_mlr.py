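"""OLS fitting against exact oracles, and the fit-statistic identities."""

from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from qsarmlr import compute_fit_stats, fit_ols, predict_mlr
from qsarmlr.mlr import RankDeficiencyError

from conftest import make_dataset


def solve_normal_equations_exact(X_rows, y):
    """Independent oracle: solve (X'X) b = X'y in exact rational arithmetic."""
    X = [[Fraction(1)] + [Fraction(v).limit_denominator(10**12) for v in row] for row in X_rows]
    yf = [Fraction(v).limit_denominator(10**12) for v in y]
    p = len(X[0])
    A = [[sum(X[i][a] * X[i][b] for i in range(len(X))) for b in range(p)] for a in range(p)]
    rhs = [sum(X[i][a] * yf[i] for i in range(len(X))) for a in range(p)]
    # Gaussian elimination with partial pivoting, exact
    for col in range(p):
        piv = max(range(col, p), key=lambda r: abs(A[r][col]))
        A[col], A[piv] = A[piv], A[col]
        rhs[col], rhs[piv] = rhs[piv], rhs[col]
        for r in range(col + 1, p):
            f = A[r][col] / A[col][col]
            for c in range(col, p):
                A[r][c] -= f * A[col][c]
            rhs[r] -= f * rhs[col]
    beta = [Fraction(0)] * p
    for r in reversed(range(p)):
        s = rhs[r] - sum(A[r][c] * beta[c] for c in range(r + 1, p))
        beta[r] = s / A[r][r]
    return [float(b) for b in beta]


def test_noiseless_line():
    x = np.array([0.0, 1.0, 2.0, 3.0, 4.0])
    ds = make_dataset(x.reshape(-1, 1))
    fit = fit_ols(ds, 2 * x + 1)
    assert fit.intercept == pytest.approx(1.0, abs=1e-12)
    assert fit.coefficients[0] == pytest.approx(2.0, abs=1e-12)
    assert fit.stats.r2 == pytest.approx(1.0, abs=1e-12)
    assert fit.stats.rmse == pytest.approx(0.0, abs=1e-9)


def test_four_point_two_descriptor_vs_exact_oracle():
    X = [[0.1, 1.0], [0.4, -0.5], [-0.3, 0.2], [0.8, 0.9]]
    y = [1.0, 2.0, 0.5, 1.7]
    expected = solve_normal_equations_exact(X, y)
    fit = fit_ols(make_dataset(X), np.asarray(y))
    got = [fit.intercept, *fit.coefficients]
    np.testing.assert_allclose(got, expected, rtol=1e-10)


@pytest.mark.parametrize("seed", range(5))
def test_random_6x2_instances_vs_exact_oracle(seed):
    rng = np.random.default_rng(seed)
    X = np.round(rng.normal(size=(6, 2)), 6)
    y = np.round(rng.normal(size=6), 6)
    expected = solve_normal_equations_exact(X.tolist(), y.tolist())
    fit = fit_ols(make_dataset(X), y)
    np.testing.assert_allclose([fit.intercept, *fit.coefficients], expected, rtol=1e-10)


def test_agrees_with_statsmodels(reference_train):
    sm = pytest.importorskip("statsmodels.api")
    fit = fit_ols(reference_train)
    X = sm.add_constant(reference_train.X)
    res = sm.OLS(reference_train.y, X).fit()
    np.testing.assert_allclose(
        [fit.intercept, *fit.coefficients], res.params, rtol=1e-10
    )
    assert fit.stats.r2 == pytest.approx(res.rsquared, rel=1e-10)
    assert fit.stats.r2_adj == pytest.approx(res.rsquared_adj, rel=1e-10)


def test_fitted_plus_residual_reconstructs_y(reference_train):
    fit = fit_ols(reference_train)
    fitted = predict_mlr(fit, reference_train)
    np.testing.assert_allclose(fitted + fit.residuals, reference_train.y, rtol=1e-12)


@settings(deadline=None, max_examples=25, derandomize=True)
@given(st.integers(0, 10**6), st.integers(5, 20), st.integers(1, 3))
def test_residuals_sum_to_zero(seed, n, k):
    rng = np.random.default_rng(seed)
    fit = fit_ols(make_dataset(rng.normal(size=(n, k))), rng.normal(size=n))
    assert abs(fit.residuals.sum()) < 1e-8
    assert fit.stats.r2_adj <= fit.stats.r2 + 1e-12


def test_rank_deficiency_names_columns():
    rng = np.random.default_rng(0)
    X = rng.normal(size=(10, 3))
    X[:, 2] = 2.0 * X[:, 0]  # exact linear dependence
    with pytest.raises(RankDeficiencyError, match="d"):
        fit_ols(make_dataset(X), rng.normal(size=10))


def test_too_few_observations():
    with pytest.raises(ValueError, match="too few"):
        fit_ols(make_dataset(np.eye(3)), np.ones(3))


def test_predict_zero_row_gives_intercept(reference_train):
    fit = fit_ols(reference_train)
    assert predict_mlr(fit, np.zeros((1, 5)))[0] == pytest.approx(fit.intercept)


def test_predict_rejects_misordered_columns(reference_train):
    fit = fit_ols(reference_train)
    shuffled = reference_train.select_descriptors(
        list(reversed(reference_train.descriptor_names))
    )
    with pytest.raises(ValueError, match="do not match"):
        predict_mlr(fit, shuffled)


def test_fit_stats_identities():
    y = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
    st_ = compute_fit_stats(y, y, k=1)
    assert st_.r2 == 1.0 and st_.rmse == 0.0
    yhat = y + np.array([0.1, -0.1, 0.2, -0.2, 0.1, -0.1])
    st2 = compute_fit_stats(y, yhat, k=2)
    assert st2.r2 == pytest.approx(1 - st2.rss / st2.tss)
    assert st2.r2_adj == pytest.approx(1 - (1 - st2.r2) * 5 / (6 - 3))
    assert st2.rmse == pytest.approx(np.sqrt(st2.rss / 6))


def test_fit_stats_rejects_constant_response():
    with pytest.raises(ValueError, match="constant"):
        compute_fit_stats(np.ones(6), np.ones(6), k=1)


def test_adjusted_r2_from_printed_inputs():
    # n=27, k=5 model with R2=0.767 must give R2_adj ~ 0.712
    r2 = 0.767
    r2_adj = 1 - (1 - r2) * (27 - 1) / (27 - 5 - 1)
    assert r2_adj == pytest.approx(0.712, abs=2e-3)
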