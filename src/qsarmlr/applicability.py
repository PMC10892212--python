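"""Leverage-based applicability domain (Williams-plot analysis).

A compound's leverage h_i = x_i' (X'X)^-1 x_i measures its distance from
the training-descriptor centroid; predictions above the warning leverage
h* = 3(k+1)/n extrapolate beyond the model's chemical space.  Combined with
standardized residuals (|r| <= 3 by convention) this classifies compounds
as inside or outside the applicability domain.

Two leverage conventions are supported.  The default augments the rows
with an intercept column, which is the textbook hat matrix: training
leverages then lie in [1/n, 1] and sum to k+1, consistent with the k+1
parameters behind h*.  ``include_intercept=False`` applies the formula to
the raw descriptor rows instead — the convention under which the published
leverages of the designed triazole candidates (e.g. P14 = 0.358) reproduce
exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .mlr import ModelFit, RankDeficiencyError, design_matrix

SIGMA_CUT_DEFAULT = 3.0


@dataclass
class ADResult:
    """Per-compound applicability-domain classification (Williams-plot data)."""

    compound_ids: list[str]
    leverages: np.ndarray
    h_star: float
    std_residuals: np.ndarray  # NaN where no observed activity (query rows)
    in_domain: np.ndarray  # bool
    outlier_response: np.ndarray  # bool, |std residual| > sigma_cut
    sigma_cut: float = SIGMA_CUT_DEFAULT

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "compound_id": self.compound_ids,
                "leverage": self.leverages,
                "h_star": self.h_star,
                "std_residual": self.std_residuals,
                "in_domain": self.in_domain,
                "outlier_response": self.outlier_response,
            }
        )


def leverages(
    X_train: np.ndarray,
    X_query: np.ndarray | None = None,
    include_intercept: bool = True,
) -> np.ndarray:
    """Leverage of each query row against the training design matrix.

    With ``X_query=None`` the training rows themselves are scored, giving
    the hat-matrix diagonal.
    """
    X_train = np.asarray(X_train, dtype=float)
    Xq = X_train if X_query is None else np.atleast_2d(np.asarray(X_query, dtype=float))
    if Xq.shape[1] != X_train.shape[1]:
        raise ValueError("query columns do not align with the training matrix")
    A = design_matrix(X_train) if include_intercept else X_train
    Q = design_matrix(Xq) if include_intercept else Xq
    s = scipy.linalg.svdvals(A)
    if s[-1] <= 1e-10 * s[0]:
        raise RankDeficiencyError("training matrix is rank-deficient")
    gram = A.T @ A
    c, low = scipy.linalg.cho_factor(gram)
    sol = scipy.linalg.cho_solve((c, low), Q.T)
    return np.einsum("ij,ji->i", Q, sol)


def warning_leverage(k: int, n: int) -> float:
    """Warning leverage h* = 3(k+1)/n for k descriptors and n training rows."""
    if n <= 0:
        raise ValueError("n must be positive")
    if k < 0:
        raise ValueError("k must be nonnegative")
    return 3.0 * (k + 1) / n


def standardized_residuals(
    fit: ModelFit,
    y_obs: np.ndarray,
    y_pred: np.ndarray,
    divisor: str = "n-k-1",
) -> np.ndarray:
    """Residuals scaled by the training residual standard error.

    ``divisor`` selects s = sqrt(RSS/(n-k-1)) (default, the conventional
    residual standard error) or ``"n"`` for s = RMSE = sqrt(RSS/n).
    Test-set residuals are standardized by the same training s.
    """
    y_obs = np.asarray(y_obs, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_obs.shape != y_pred.shape:
        raise ValueError("observed and predicted vectors are not aligned")
    n, k = fit.stats.n, fit.stats.k
    if n <= k + 1:
        raise ValueError("residual standard error undefined: n <= k+1")
    if divisor == "n-k-1":
        s = np.sqrt(fit.stats.rss / (n - k - 1))
    elif divisor == "n":
        s = fit.stats.rmse
    else:
        raise ValueError("divisor must be 'n-k-1' or 'n'")
    return (y_obs - y_pred) / s


def williams_classification(
    compound_ids: list[str],
    lev: np.ndarray,
    h_star: float,
    std_resid: np.ndarray | None = None,
    sigma_cut: float = SIGMA_CUT_DEFAULT,
) -> ADResult:
    """Classify compounds from leverage and (where defined) standardized residual.

    In-domain means h <= h* and, when a residual is defined, |r| <= sigma_cut.
    Query compounds (NaN residual) are classified on leverage alone.  The
    boundary h = h* counts as inside.
    """
    lev = np.asarray(lev, dtype=float)
    if std_resid is None:
        std_resid = np.full(lev.size, np.nan)
    std_resid = np.asarray(std_resid, dtype=float)
    if len(compound_ids) != lev.size or std_resid.size != lev.size:
        raise ValueError("compound ids, leverages and residuals are not aligned")
    has_resid = np.isfinite(std_resid)
    outlier = has_resid & (np.abs(std_resid) > sigma_cut)
    in_domain = (lev <= h_star) & ~outlier
    return ADResult(
        compound_ids=list(compound_ids),
        leverages=lev,
        h_star=h_star,
        std_residuals=std_resid,
        in_domain=in_domain,
        outlier_response=outlier,
        sigma_cut=sigma_cut,
    )
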