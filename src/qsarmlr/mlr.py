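"""Ordinary-least-squares multiple linear regression for QSAR models.

The model is y = a0 + a1*x1 + ... + ak*xk in raw descriptor units (no
scaling).  Fitting goes through an orthogonal decomposition (LAPACK
``gelsd`` via :func:`scipy.linalg.lstsq`); rank deficiency is detected from
the singular-value spectrum and reported with the offending columns.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .datasets import DescriptorDataset

#: Singular values below RANK_RTOL x largest mark the design as deficient.
RANK_RTOL = 1e-10


class RankDeficiencyError(np.linalg.LinAlgError):
    """Design matrix is numerically rank-deficient."""


@dataclass
class FitStats:
    """Goodness-of-fit summary of an OLS fit.

    ``rmse`` uses divisor ``n`` (root of the mean squared training
    residual), the convention under which the reference model's printed
    0.082 reproduces.
    """

    r2: float
    r2_adj: float
    rmse: float
    rss: float
    tss: float
    k: int
    n: int


@dataclass
class ModelFit:
    """A fitted MLR model: selected descriptors, coefficients and stats."""

    descriptor_names: list[str]
    intercept: float
    coefficients: np.ndarray
    n_train: int
    residuals: np.ndarray
    stats: FitStats
    y_train_mean: float

    @property
    def k(self) -> int:
        return len(self.descriptor_names)

    def equation(self, digits: int = 3) -> str:
        """Human-readable model equation, e.g. ``pIC50 = 6.403 + 0.759 AATSC8s ...``"""
        terms = [f"{self.intercept:.{digits}f}"]
        for name, a in zip(self.descriptor_names, self.coefficients):
            sign = "+" if a >= 0 else "-"
            terms.append(f"{sign} {abs(a):.{digits}f} {name}")
        return "pIC50 = " + " ".join(terms)


def design_matrix(X: np.ndarray) -> np.ndarray:
    """Prepend the intercept column of ones."""
    X = np.asarray(X, dtype=float)
    return np.column_stack([np.ones(X.shape[0]), X])


def _check_rank(Xd: np.ndarray, names: list[str]) -> None:
    s = scipy.linalg.svdvals(Xd)
    if s[-1] <= RANK_RTOL * s[0]:
        # identify dependent columns through pivoted QR
        _, _, piv = scipy.linalg.qr(Xd, pivoting=True, mode="economic")
        rank = int(np.sum(s > RANK_RTOL * s[0]))
        cols = ["intercept"] + list(names)
        dependent = sorted(cols[i] for i in piv[rank:])
        raise RankDeficiencyError(
            f"design matrix is rank-deficient; dependent columns: {dependent}"
        )


def fit_ols(ds: DescriptorDataset, y: np.ndarray | None = None) -> ModelFit:
    """Fit an intercept-containing OLS model on all rows of ``ds``.

    Parameters
    ----------
    ds
        Dataset already restricted to the selected descriptor subset
        (typically the training rows).
    y
        Activity vector; defaults to ``ds.y``.

    Raises
    ------
    RankDeficiencyError
        If the intercept-augmented design matrix is numerically singular.
    ValueError
        If there are too few observations (n <= k + 1).
    """
    if y is None:
        if ds.y is None:
            raise ValueError("no activity vector available")
        y = ds.y
    y = np.asarray(y, dtype=float)
    n, k = ds.X.shape
    if y.shape != (n,):
        raise ValueError("y is not aligned with the dataset rows")
    if not np.all(np.isfinite(y)):
        raise ValueError("y contains non-finite values")
    if n <= k + 1:
        raise ValueError(f"too few observations: n={n} <= k+1={k + 1}")
    Xd = design_matrix(ds.X)
    _check_rank(Xd, ds.descriptor_names)
    beta, *_ = scipy.linalg.lstsq(Xd, y, lapack_driver="gelsd")
    fitted = Xd @ beta
    residuals = y - fitted
    stats = compute_fit_stats(y, fitted, k)
    return ModelFit(
        descriptor_names=list(ds.descriptor_names),
        intercept=float(beta[0]),
        coefficients=beta[1:].copy(),
        n_train=n,
        residuals=residuals,
        stats=stats,
        y_train_mean=float(np.mean(y)),
    )


def predict_mlr(model: ModelFit, X_new, descriptor_names: list[str] | None = None) -> np.ndarray:
    """Apply a fitted model to new descriptor rows.

    ``X_new`` may be a :class:`DescriptorDataset` (column names are checked
    against the model) or a bare matrix accompanied by ``descriptor_names``.
    Columns must match the model's descriptors exactly and in order.
    """
    if isinstance(X_new, DescriptorDataset):
        names = X_new.descriptor_names
        X = X_new.X
    else:
        names = descriptor_names
        X = np.asarray(X_new, dtype=float)
    if names is not None and list(names) != list(model.descriptor_names):
        raise ValueError(
            f"descriptor columns {list(names)} do not match the model's "
            f"{model.descriptor_names} (same names, same order required)"
        )
    X = np.atleast_2d(X)
    if X.shape[1] != model.k:
        raise ValueError(f"expected {model.k} descriptor columns, got {X.shape[1]}")
    return model.intercept + X @ model.coefficients


def compute_fit_stats(y: np.ndarray, y_fitted: np.ndarray, k: int) -> FitStats:
    """R2, adjusted R2 and RMSE of fitted values against observations.

    TSS is computed about the mean of ``y``; a constant response (zero TSS)
    is rejected because R2 is undefined there.
    """
    y = np.asarray(y, dtype=float)
    y_fitted = np.asarray(y_fitted, dtype=float)
    if y.shape != y_fitted.shape:
        raise ValueError("observed and fitted vectors are not aligned")
    n = y.size
    if n <= k + 1:
        raise ValueError(f"too few observations: n={n} <= k+1={k + 1}")
    rss = float(np.sum((y - y_fitted) ** 2))
    tss = float(np.sum((y - y.mean()) ** 2))
    if tss == 0.0:
        raise ValueError("constant response: total sum of squares is zero")
    r2 = 1.0 - rss / tss
    r2_adj = 1.0 - (1.0 - r2) * (n - 1) / (n - k - 1)
    rmse = float(np.sqrt(rss / n))
    return FitStats(r2=r2, r2_adj=r2_adj, rmse=rmse, rss=rss, tss=tss, k=k, n=n)
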