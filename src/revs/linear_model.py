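"""Ordinary least squares on a predictor subset, plus the model-quality
statistics (R², adjusted R², Gaussian log-likelihood, AIC, overall F-test)
consumed by the ranking and model-comparison stages.

Fits are delegated to :class:`statsmodels.api.OLS` (pinv-based, so exact
multicollinearity yields the minimum-norm solution rather than a failure);
the information-criterion arithmetic is kept explicit here because the AIC
parameter count is a documented convention of this package: ``K = k + 2``
counts the intercept and the residual variance alongside the ``k`` slopes.
Delta AICs — the only AIC-derived quantity the selection stages use — are
identical under the slope-only convention ``K = k``, since the two differ
by a constant 4 for every model on the same data.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .dataset import Dataset

__all__ = [
    "FitSummary",
    "fit_subset",
    "adjusted_r2",
    "gaussian_loglik",
    "aic_gaussian",
    "overall_significance",
    "predict",
    "DegenerateFitWarning",
    "InsufficientCasesError",
]

#: rss below this fraction of the total sum of squares counts as a perfect
#: (degenerate-likelihood) fit.
PERFECT_FIT_RTOL = 1e-12


class InsufficientCasesError(ValueError):
    """Raised when a fit is requested with n <= k + 1 cases."""


class DegenerateFitWarning(UserWarning):
    """Warned when a design is rank-deficient or a fit is numerically perfect."""


@dataclass(frozen=True)
class FitSummary:
    """One OLS fit of the response on a predictor subset.

    Attributes
    ----------
    subset : tuple of int
        Ordered predictor column indices (size ``k >= 0``).
    names : tuple of str
        Labels matching ``subset``.
    coefficients : ndarray, shape (k + 1,)
        Intercept followed by slopes, in ``subset`` order.
    rss : float
        Residual sum of squares (response units squared).
    r2, adj_r2 : float
        Coefficient of determination and its adjusted form.
    loglik, aic : float
        Gaussian maximum log-likelihood and ``-2 loglik + 2K``; ``aic`` is
        NaN for a numerically perfect fit (degenerate likelihood).
    K : int
        Parameter count used in the AIC (``k + 2``).
    f_stat, p_value : float
        Overall model F statistic and its p-value (1.0 for ``k = 0``).
    n : int
        Cases fitted.
    degenerate : bool
        True if the design was rank-deficient (minimum-norm solution used).
    """

    subset: tuple[int, ...]
    names: tuple[str, ...]
    coefficients: np.ndarray
    rss: float
    r2: float
    adj_r2: float
    loglik: float
    aic: float
    K: int
    f_stat: float
    p_value: float
    n: int
    degenerate: bool = False

    @property
    def k(self) -> int:
        """Number of predictors in the model."""
        return len(self.subset)

    @property
    def intercept(self) -> float:
        return float(self.coefficients[0])

    @property
    def slopes(self) -> np.ndarray:
        return self.coefficients[1:]


def adjusted_r2(r2: float, n: int, k: int) -> float:
    """Wherry/Ezekiel adjusted R²: ``1 - (1 - R²)(n - 1)/(n - k - 1)``.

    Equals ``r2`` when ``k = 0`` and never exceeds it otherwise.
    """
    if n <= k + 1:
        raise InsufficientCasesError(
            f"insufficient cases: n={n} <= k+1={k + 1}"
        )
    return 1.0 - (1.0 - r2) * (n - 1) / (n - k - 1)


def gaussian_loglik(rss: float, n: int) -> float:
    """Maximised Gaussian log-likelihood ``-(n/2)(ln 2π + ln(rss/n) + 1)``."""
    if rss <= 0:
        raise ValueError("degenerate likelihood: rss must be positive")
    if n <= 0:
        raise ValueError("n must be positive")
    return -0.5 * n * (math.log(2 * math.pi) + math.log(rss / n) + 1.0)


def aic_gaussian(
    rss: float, n: int, k_predictors: int, convention: str = "full"
) -> float:
    """Akaike Information Criterion ``-2 loglik + 2K`` for a Gaussian fit.

    Parameters
    ----------
    convention : {"full", "slopes"}
        "full" counts ``K = k + 2`` parameters (slopes, intercept, residual
        variance); "slopes" counts only the ``K = k`` slopes.  The two give
        delta AICs that agree exactly, differing by a constant 4 on any
        fixed dataset.
    """
    if n < 2:
        raise ValueError("n must be at least 2")
    if convention == "full":
        K = k_predictors + 2
    elif convention == "slopes":
        K = k_predictors
    else:
        raise ValueError(f"unknown AIC convention {convention!r}")
    return -2.0 * gaussian_loglik(rss, n) + 2.0 * K


def overall_significance(r2: float, n: int, k: int) -> tuple[float, float]:
    """Overall model F statistic and p-value.

    ``F = (R²/k) / ((1-R²)/(n-k-1))`` on ``(k, n-k-1)`` degrees of freedom.
    For the intercept-only model (``k = 0``) the test is undefined and
    ``(nan, 1.0)`` is returned by convention.
    """
    if k == 0:
        return math.nan, 1.0
    if n <= k + 1:
        raise InsufficientCasesError(
            f"insufficient cases: n={n} <= k+1={k + 1}"
        )
    if r2 >= 1.0:
        return math.inf, 0.0
    f = (r2 / k) / ((1.0 - r2) / (n - k - 1))
    return f, float(stats.f.sf(f, k, n - k - 1))


def fit_subset(data: Dataset, subset: Sequence[int]) -> FitSummary:
    """Fit OLS of the response on the given predictor columns.

    ``subset`` may be empty (intercept-only null model).  Exact
    multicollinearity within the subset does not abort the fit: the
    minimum-norm coefficient vector is returned, ``degenerate`` is set and
    a :class:`DegenerateFitWarning` is issued.

    Raises
    ------
    InsufficientCasesError
        If ``n <= k + 1``.
    ValueError
        If subset indices are invalid or repeated.
    """
    subset = tuple(int(i) for i in subset)
    if len(set(subset)) != len(subset):
        raise ValueError("subset indices must be distinct")
    if any(not 0 <= i < data.p for i in subset):
        raise ValueError(f"subset indices out of range 0..{data.p - 1}")
    k, n = len(subset), data.n
    if n <= k + 1:
        raise InsufficientCasesError(
            f"insufficient cases: n={n} <= k+1={k + 1}"
        )
    y = data.response
    tss = float(np.sum((y - y.mean()) ** 2))

    if k == 0:
        coefs = np.array([y.mean()])
        rss = tss
        aic = aic_gaussian(rss, n, 0) if rss > 0 else math.nan
        return FitSummary(
            subset=(), names=(), coefficients=coefs, rss=rss, r2=0.0,
            adj_r2=0.0, loglik=gaussian_loglik(rss, n) if rss > 0 else math.inf,
            aic=aic, K=2, f_stat=math.nan, p_value=1.0, n=n,
        )

    X = sm.add_constant(data.predictors[:, subset], has_constant="add")
    res = sm.OLS(y, X).fit()
    degenerate = res.df_model < k
    if degenerate:
        warnings.warn(
            f"rank-deficient design for subset {subset}; "
            "minimum-norm solution returned",
            DegenerateFitWarning,
            stacklevel=2,
        )
    rss = float(res.ssr)
    r2 = min(max(float(res.rsquared), 0.0), 1.0) if tss > 0 else 0.0
    perfect = rss <= PERFECT_FIT_RTOL * max(tss, 1.0)
    if perfect:
        warnings.warn(
            f"numerically perfect fit for subset {subset}; AIC undefined",
            DegenerateFitWarning,
            stacklevel=2,
        )
        loglik, aic = math.inf, math.nan
    else:
        loglik = gaussian_loglik(rss, n)
        aic = aic_gaussian(rss, n, k)
    f_stat, p_value = overall_significance(r2, n, k)
    return FitSummary(
        subset=subset,
        names=tuple(data.predictor_names[i] for i in subset),
        coefficients=np.asarray(res.params, dtype=float),
        rss=rss,
        r2=r2,
        adj_r2=adjusted_r2(r2, n, k),
        loglik=loglik,
        aic=aic,
        K=k + 2,
        f_stat=f_stat,
        p_value=p_value,
        n=n,
        degenerate=bool(degenerate),
    )


def predict(fit: FitSummary, new_predictors) -> np.ndarray:
    """Predict the response for new cases from a fitted subset model.

    ``new_predictors`` is either a DataFrame containing (at least) the
    columns named in ``fit.names``, or an array whose columns are already
    in ``fit.subset`` order — for an array with the full original predictor
    count, ``fit.subset`` is used to select columns.
    """
    if isinstance(new_predictors, pd.DataFrame):
        missing = [c for c in fit.names if c not in new_predictors.columns]
        if missing:
            raise KeyError(f"missing required column(s): {missing}")
        X = new_predictors[list(fit.names)].to_numpy(dtype=float)
    else:
        X = np.atleast_2d(np.asarray(new_predictors, dtype=float))
        if X.shape[1] != fit.k:
            if fit.subset and X.shape[1] > max(fit.subset):
                X = X[:, list(fit.subset)]
            else:
                raise ValueError(
                    f"expected {fit.k} predictor columns, got {X.shape[1]}"
                )
    return fit.intercept + X @ fit.slopes
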