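"""LOO cross-validation, external metrics and the Y-randomization null."""

import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from qsarmlr import (
    SyntheticSpec,
    crp2,
    external_metrics,
    fit_ols,
    generate_dataset,
    predict_mlr,
    q2_loo,
    validate_model,
    y_randomization,
)

from conftest import make_dataset


def literal_loo_press(X, y):
    """Oracle: leave-one-out PRESS by n explicit refits."""
    n = len(y)
    press = 0.0
    for i in range(n):
        keep = np.arange(n) != i
        Xd = np.column_stack([np.ones(n - 1), X[keep]])
        beta, *_ = np.linalg.lstsq(Xd, y[keep], rcond=None)
        pred = beta[0] + X[i] @ beta[1:]
        press += (y[i] - pred) ** 2
    return press


def test_noiseless_planted_data_gives_q2_of_one():
    ds, truth = generate_dataset(
        SyntheticSpec(
            n_compounds=40,
            n_descriptors=6,
            informative_subset=(0, 2),
            true_intercept=1.0,
            true_coefficients=(2.0, -1.0),
            noise_sd=0.0,
            seed=3,
        )
    )
    q2, press = q2_loo(ds.select_descriptors(truth.informative_names), ds.y)
    assert q2 == pytest.approx(1.0, abs=1e-10)
    assert press == pytest.approx(0.0, abs=1e-10)


@settings(deadline=None, max_examples=20, derandomize=True)
@given(st.integers(0, 10**6))
def test_shortcut_equals_literal_refits(seed):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(10, 2))
    y = rng.normal(size=10)
    q2, press = q2_loo(make_dataset(X), y)
    oracle = literal_loo_press(X, y)
    assert press == pytest.approx(oracle, rel=1e-10)


def test_q2_never_exceeds_r2(rng):
    for _ in range(10):
        X = rng.normal(size=(25, 3))
        y = rng.normal(size=25)
        ds = make_dataset(X)
        q2, _ = q2_loo(ds, y)
        assert q2 <= fit_ols(ds, y).stats.r2 + 1e-12


def test_q2_decreases_with_noise_in_expectation():
    def mean_q2(noise):
        vals = []
        for seed in range(10):
            ds, truth = generate_dataset(
                SyntheticSpec(
                    n_compounds=60,
                    n_descriptors=8,
                    informative_subset=(0, 1),
                    true_intercept=0.0,
                    true_coefficients=(1.0, -1.0),
                    noise_sd=noise,
                    seed=seed,
                )
            )
            vals.append(q2_loo(ds.select_descriptors(truth.informative_names), ds.y)[0])
        return np.mean(vals)

    assert mean_q2(0.1) > mean_q2(0.8) > mean_q2(2.5)


def test_q2_requires_enough_rows():
    with pytest.raises(ValueError, match="LOO"):
        q2_loo(make_dataset(np.eye(4)[:, :2]), np.ones(4))


def test_external_metrics_perfect_prediction(reference_train):
    fit = fit_ols(reference_train)
    fake_test = reference_train.subset_rows(np.arange(27) < 5)
    fake_test.y = predict_mlr(fit, fake_test)  # observations equal predictions
    m = external_metrics(fit, fake_test)
    for v in (m.q2_f1, m.q2_f2, m.q2_f3, m.r2_pearson_test):
        assert v == pytest.approx(1.0, abs=1e-9)


def test_external_q2f1_matches_direct_formula(reference_train):
    fit = fit_ols(reference_train)
    X = np.array([[0.1, -3.0, 0.0, 1.2, 0.1], [0.0, -5.0, 1.0, 1.5, 0.2], [-0.1, -7.0, 0.0, 1.0, 0.15]])
    y = np.array([5.5, 5.3, 5.6])
    test = make_dataset(X)
    test.descriptor_names = list(reference_train.descriptor_names)
    pred = predict_mlr(fit, X)
    expected = 1 - np.sum((y - pred) ** 2) / np.sum((y - np.mean(reference_train.y)) ** 2)
    m = external_metrics(fit, test, y)
    assert m.q2_f1 == pytest.approx(expected, rel=1e-12)


def test_external_single_compound_pearson_undefined(reference_train):
    fit = fit_ols(reference_train)
    single = reference_train.subset_rows(np.arange(27) == 0)
    m = external_metrics(fit, single)
    assert np.isnan(m.r2_pearson_test) and np.isnan(m.q2_f2)
    assert np.isfinite(m.q2_f1) and np.isfinite(m.q2_f3)


def test_yrandomization_seeded_and_reproducible(reference_train):
    a = y_randomization(reference_train, n_iterations=60, seed=9)
    b = y_randomization(reference_train, n_iterations=60, seed=9)
    np.testing.assert_array_equal(a.r2_values, b.r2_values)
    assert a.mean_r2 == pytest.approx(np.mean(a.r2_values))
    assert a.mean_q2 == pytest.approx(np.mean(a.q2_values))
    c = y_randomization(reference_train, n_iterations=60, seed=10)
    assert not np.array_equal(a.r2_values, c.r2_values)


def test_unpermuted_first_iteration_reproduces_model(reference_train):
    fit = fit_ols(reference_train)
    res = y_randomization(
        reference_train, n_iterations=50, seed=0, include_unpermuted_first=True
    )
    assert res.r2_values[0] == pytest.approx(fit.stats.r2, rel=1e-12)


def test_yrandomization_mean_r2_matches_permutation_expectation():
    """For a random response, E[R^2] of a k-descriptor OLS fit is k/(n-1)."""
    rng = np.random.default_rng(42)
    ds = make_dataset(rng.normal(size=(60, 3)))
    y = rng.normal(size=60)
    res = y_randomization(ds, y, n_iterations=300, seed=1)
    assert res.mean_r2 == pytest.approx(3 / 59, abs=0.012)


def test_yrandomization_minimum_iterations(reference_train):
    with pytest.raises(ValueError):
        y_randomization(reference_train, n_iterations=10, seed=0)


def test_crp2_limit_cases():
    assert crp2(0.8, 0.0) == pytest.approx(0.64)
    assert crp2(0.5, 0.5) == pytest.approx(0.0)
    with pytest.warns(UserWarning):
        assert crp2(0.3, 0.5) == 0.0


def test_crp2_printed_combination():
    # R and the randomized mean correlation of the reference model
    assert crp2(np.sqrt(0.767), 0.428) == pytest.approx(0.669, abs=0.005)


def test_validate_model_report(reference):
    train = reference.synthesized.training_set()
    test = reference.synthesized.test_set()
    with warnings.catch_warnings():
        warnings.simplefilter("error")  # no truncation warning expected here
        rep = validate_model(train, test, n_iterations=60, seed=4)
    assert rep.q2_loo < fit_ols(train).stats.r2
    assert rep.external.n_test == 6
    assert rep.yrand.n_iterations == 60
    assert not rep.notes
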