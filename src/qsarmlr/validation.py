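"""Internal and external model validation, plus the Y-randomization null.

Internal validation is the leave-one-out cross-validated determination
coefficient Q2_LOO = 1 - PRESS/TSS, with PRESS computed through the exact
hat-matrix shortcut (each deleted residual is e_i / (1 - h_ii)); external
validation reports the full family of test-set metrics because the
literature's single "R2_ext" is ambiguous.  Y-randomization refits the same
descriptor subset against seeded permutations of the activity and summarises
the chance baseline through mean R, R2, Q2 and the corrected cRp2
statistic R * sqrt(R2 - mean_r^2).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from .datasets import DescriptorDataset
from .mlr import ModelFit, RankDeficiencyError, design_matrix, fit_ols, predict_mlr


@dataclass
class ExternalMetrics:
    """Test-set predictivity metrics.

    ``q2_f1`` normalises the test-set press by deviations of the test
    observations about the *training* mean; ``q2_f2`` about the test mean;
    ``q2_f3`` compares per-observation mean squared errors (test PRESS / n_ext
    against training TSS / n_train); ``r2_pearson_test`` is the squared
    Pearson correlation of observed vs predicted on the test set (undefined,
    NaN, for fewer than two test compounds).
    """

    q2_f1: float
    q2_f2: float
    q2_f3: float
    r2_pearson_test: float
    n_test: int


@dataclass
class YRandResult:
    """Summary of the Y-randomization (response-scrambling) null."""

    n_iterations: int
    seed: int
    r_values: np.ndarray
    r2_values: np.ndarray
    q2_values: np.ndarray
    mean_r: float
    mean_r2: float
    mean_q2: float
    crp2: float
    crp2_truncated: bool = False


@dataclass
class ValidationReport:
    """Everything the validation stage computes for one model."""

    q2_loo: float
    press: float
    external: ExternalMetrics | None
    yrand: YRandResult | None
    notes: list[str] = field(default_factory=list)


def hat_diagonal(X: np.ndarray, include_intercept: bool = True) -> np.ndarray:
    """Diagonal of the hat (projection) matrix H = X (X'X)^-1 X'."""
    Xd = design_matrix(X) if include_intercept else np.asarray(X, dtype=float)
    q, r = scipy.linalg.qr(Xd, mode="economic")
    if abs(r[-1, -1]) <= 1e-10 * abs(r[0, 0]):
        raise RankDeficiencyError("design matrix is rank-deficient")
    return np.sum(q * q, axis=1)


def q2_loo(ds: DescriptorDataset, y: np.ndarray | None = None) -> tuple[float, float]:
    """Leave-one-out Q2 and PRESS for an OLS fit on ``ds``.

    PRESS = sum_i (e_i / (1 - h_ii))^2 — algebraically identical to
    refitting n times with one compound deleted.  TSS is about the full
    training mean (standard PRESS convention).
    """
    if y is None:
        y = ds.y
    y = np.asarray(y, dtype=float)
    n, k = ds.X.shape
    if n <= k + 2:
        raise ValueError(f"too few observations for LOO: n={n} <= k+2={k + 2}")
    fit = fit_ols(ds, y)
    h = hat_diagonal(ds.X)
    if np.any(h >= 1.0 - 1e-12):
        raise RankDeficiencyError(
            "a leave-one-out fold is rank-deficient (leverage of 1)"
        )
    deleted = fit.residuals / (1.0 - h)
    press = float(np.sum(deleted**2))
    tss = float(np.sum((y - y.mean()) ** 2))
    return 1.0 - press / tss, press


def external_metrics(
    model: ModelFit, test: DescriptorDataset, y_test: np.ndarray | None = None
) -> ExternalMetrics:
    """Test-set predictivity of a fitted model (see class docstring)."""
    if y_test is None:
        y_test = test.y
    y_test = np.asarray(y_test, dtype=float)
    if test.n_compounds == 0:
        raise ValueError("empty test set")
    pred = predict_mlr(model, test)
    press_ext = float(np.sum((y_test - pred) ** 2))
    n_ext = test.n_compounds
    ybar_train = model.y_train_mean
    q2_f1 = 1.0 - press_ext / float(np.sum((y_test - ybar_train) ** 2))
    if n_ext >= 2 and np.std(y_test) > 0:
        q2_f2 = 1.0 - press_ext / float(np.sum((y_test - y_test.mean()) ** 2))
        r = float(np.corrcoef(y_test, pred)[0, 1])
        r2p = r * r
    else:
        q2_f2 = float("nan")
        r2p = float("nan")
    q2_f3 = 1.0 - (press_ext / n_ext) / (model.stats.tss / model.stats.n)
    return ExternalMetrics(
        q2_f1=q2_f1, q2_f2=q2_f2, q2_f3=q2_f3, r2_pearson_test=r2p, n_test=n_ext
    )


def crp2(R: float, mean_r_random: float) -> float:
    """Corrected randomization parameter cRp2 = R * sqrt(R^2 - mean_r^2).

    ``mean_r_random`` is the mean correlation of the randomized models.  A
    negative radicand (model no better than chance) is truncated to zero
    with a warning.
    """
    rad = R * R - mean_r_random * mean_r_random
    if rad < 0:
        warnings.warn(
            "cRp2 radicand negative (model correlation below the random mean); "
            "reporting 0",
            stacklevel=2,
        )
        return 0.0
    return float(R * np.sqrt(rad))


def y_randomization(
    ds: DescriptorDataset,
    y: np.ndarray | None = None,
    n_iterations: int = 500,
    seed: int = 0,
    include_unpermuted_first: bool = False,
) -> YRandResult:
    """Refit the same descriptor subset against permuted activities.

    Each iteration draws a uniform random permutation of ``y`` (seeded
    stream), refits OLS, and records R (the correlation of fitted vs
    permuted observations, i.e. sqrt(R2)), R2 and Q2_LOO.  With
    ``include_unpermuted_first`` the first iteration uses the original
    (unpermuted) response, which must reproduce the model's own statistics.
    """
    if n_iterations < 50:
        raise ValueError("n_iterations must be at least 50 for stable averages")
    if y is None:
        y = ds.y
    y = np.asarray(y, dtype=float)
    rng = np.random.default_rng(seed)
    r2s = np.empty(n_iterations)
    q2s = np.empty(n_iterations)
    for it in range(n_iterations):
        if it == 0 and include_unpermuted_first:
            yp = y
        else:
            yp = y[rng.permutation(y.size)]
        fit = fit_ols(ds, yp)
        r2s[it] = fit.stats.r2
        q2s[it], _ = q2_loo(ds, yp)
    rs = np.sqrt(np.clip(r2s, 0.0, None))
    mean_r = float(rs.mean())
    # cRp2 contrasts the real model's correlation with the random mean
    real_fit = fit_ols(ds, y)
    R = float(np.sqrt(max(real_fit.stats.r2, 0.0)))
    rad = R * R - mean_r * mean_r
    truncated = rad < 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        value = crp2(R, mean_r)
    return YRandResult(
        n_iterations=n_iterations,
        seed=seed,
        r_values=rs,
        r2_values=r2s,
        q2_values=q2s,
        mean_r=mean_r,
        mean_r2=float(r2s.mean()),
        mean_q2=float(q2s.mean()),
        crp2=value,
        crp2_truncated=truncated,
    )


def validate_model(
    train: DescriptorDataset,
    test: DescriptorDataset | None = None,
    n_iterations: int = 500,
    seed: int = 0,
) -> ValidationReport:
    """Full internal/external/Y-randomization validation of one subset.

    ``train`` (and ``test``) must already be restricted to the selected
    descriptors and carry activities.
    """
    q2, press = q2_loo(train)
    fit = fit_ols(train)
    ext = external_metrics(fit, test) if test is not None and test.n_compounds else None
    yr = y_randomization(train, n_iterations=n_iterations, seed=seed)
    notes = []
    if q2 > fit.stats.r2 + 1e-9:
        notes.append("Q2_LOO exceeds R2 (unexpected; check the data)")
    return ValidationReport(q2_loo=q2, press=press, external=ext, yrand=yr, notes=notes)
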