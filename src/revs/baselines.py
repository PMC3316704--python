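"""Comparator methods and the split-sample ("honest") validation protocol.

The empirical-ranking series is benchmarked against the three approaches it
is meant to improve on: the full model (all predictors at once), classical
one-at-a-time stepwise selection (p-value or AIC drop-of-2 criterion), and
an all-subsets comparator (the lowest-AIC model among the per-level best
subsets).  Prediction accuracy is assessed by removing a random hold-out
sample, refitting every method on the remaining cases only, predicting the
held-out responses, and regressing predicted against actual values: that
regression's R² is the honest fit estimate and its residual sum of squares
the honest error rate.  The raw sum of squared prediction errors is
reported alongside, since either reading of "hold-out RSS" may be wanted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .dataset import Dataset
from .engine import delta_aics, run_revs
from .linear_model import (
    FitSummary,
    InsufficientCasesError,
    fit_subset,
    predict,
)
from .search import level_matrix

__all__ = [
    "HoldoutSplit",
    "MethodComparison",
    "fit_full_model",
    "stepwise",
    "best_all_subsets_model",
    "make_holdout_split",
    "honest_validation",
    "compare_methods",
    "METHOD_LABELS",
]

METHOD_LABELS = ("REVS", "all-subsets", "stepwise", "full")


def fit_full_model(data: Dataset) -> FitSummary:
    """Regress the response on the complete suite of predictors."""
    if data.n <= data.p + 1:
        raise InsufficientCasesError(
            f"insufficient cases: n={data.n} <= p+1={data.p + 1}"
        )
    return fit_subset(data, range(data.p))


def _coef_pvalues(data: Dataset, subset: Sequence[int]) -> np.ndarray:
    """Per-term t-test p-values (slopes only) for the subset model."""
    X = sm.add_constant(data.predictors[:, list(subset)], has_constant="add")
    res = sm.OLS(data.response, X).fit()
    return np.asarray(res.pvalues)[1:]


def stepwise(
    data: Dataset,
    direction: str = "forward",
    criterion: str = "pvalue",
    alpha: float = 0.05,
    min_drop: float = 2.0,
) -> FitSummary:
    """Classical one-at-a-time stepwise selection.

    Parameters
    ----------
    direction : {"forward", "backward", "both"}
        Forward adds the strongest candidate while it meets the criterion;
        backward starts from the full model and removes the weakest; "both"
        allows removals after every forward step.
    criterion : {"pvalue", "aic"}
        "pvalue": enter when the candidate's partial t-test p-value is
        below ``alpha`` (remove when above).  "aic": a step is accepted
        only when it lowers the AIC by at least ``min_drop`` (the classic
        drop-of-2 rule); under this criterion at least one predictor is
        always entered in forward mode when any addition lowers AIC.

    Returns
    -------
    FitSummary
        The terminal model.  Under the p-value criterion this may be the
        intercept-only fit (with a warning) when no candidate qualifies.
    """
    if direction not in ("forward", "backward", "both"):
        raise ValueError(f"unknown direction {direction!r}")
    if criterion not in ("pvalue", "aic"):
        raise ValueError(f"unknown criterion {criterion!r}")

    current: list[int] = (
        list(range(data.p)) if direction == "backward" else []
    )

    def try_add() -> bool:
        candidates = [j for j in range(data.p) if j not in current]
        if not candidates or data.n <= len(current) + 2:
            return False
        if criterion == "pvalue":
            scored = []
            for j in candidates:
                pvals = _coef_pvalues(data, current + [j])
                scored.append((pvals[-1], j))
            best_p, best_j = min(scored)
            if best_p < alpha:
                current.append(best_j)
                return True
            return False
        base_aic = fit_subset(data, current).aic
        scored = [(fit_subset(data, current + [j]).aic, j) for j in candidates]
        best_aic, best_j = min(scored)
        if best_aic <= base_aic - min_drop:
            current.append(best_j)
            return True
        return False

    def try_remove() -> bool:
        if not current:
            return False
        if criterion == "pvalue":
            pvals = _coef_pvalues(data, current)
            worst = int(np.argmax(pvals))
            if pvals[worst] > alpha:
                del current[worst]
                return True
            return False
        base_aic = fit_subset(data, current).aic
        scored = [
            (fit_subset(data, [v for v in current if v != j]).aic, j)
            for j in current
        ]
        best_aic, best_j = min(scored)
        # a variable is retained only if keeping it beats dropping it by
        # at least min_drop
        if best_aic < base_aic + min_drop:
            current.remove(best_j)
            return True
        return False

    if direction == "forward":
        while try_add():
            pass
    elif direction == "backward":
        while try_remove():
            pass
    else:
        while try_add():
            while try_remove():
                pass
    if not current and criterion == "pvalue":
        warnings.warn(
            "no predictor met the entry criterion; returning the "
            "intercept-only model",
            UserWarning,
            stacklevel=2,
        )
    return fit_subset(data, current)


def best_all_subsets_model(data: Dataset, **level_kwargs) -> FitSummary:
    """All-subsets comparator: the lowest-AIC model among the p level-best
    subsets."""
    matrix = level_matrix(data, **level_kwargs)
    fits = [
        fit_subset(data, matrix.subset_at_level(k))
        for k in range(1, data.p + 1)
    ]
    return min(fits, key=lambda f: (f.aic if np.isfinite(f.aic) else np.inf))


@dataclass(frozen=True)
class HoldoutSplit:
    """Disjoint training / hold-out case indices with the seed that made them."""

    training: tuple[int, ...]
    holdout: tuple[int, ...]
    seed: int

    def __post_init__(self) -> None:
        if set(self.training) & set(self.holdout):
            raise ValueError("training and holdout indices overlap")


def make_holdout_split(n: int, h: int, seed: int) -> HoldoutSplit:
    """Remove ``h`` cases uniformly at random to form a hold-out sample.

    Reproducible for a fixed seed.  Requires ``2 <= h <= n - 3`` so that
    both the hold-out regression and at least a minimal training fit are
    possible.
    """
    if not 2 <= h <= n - 3:
        raise ValueError(f"holdout size h={h} out of range [2, {n - 3}]")
    rng = np.random.default_rng(seed)
    holdout = np.sort(rng.choice(n, size=h, replace=False))
    training = np.setdiff1d(np.arange(n), holdout)
    return HoldoutSplit(
        tuple(int(i) for i in training),
        tuple(int(i) for i in holdout),
        seed,
    )


@dataclass(frozen=True)
class MethodComparison:
    """Per-method comparison table (full-data fits + optional hold-out).

    ``rows`` maps a method label to a dict with keys ``k``, ``subset``,
    ``names``, ``adj_r2``, ``aic``, ``delta_aic``, ``p_value`` and — when a
    hold-out was requested — ``honest_r2``, ``honest_rss`` (residual SS of
    the predicted-vs-actual regression) and ``prediction_error_ss`` (raw
    sum of squared prediction errors).
    """

    rows: Mapping[str, dict]
    holdout: HoldoutSplit | None = None
    labels: tuple[str, ...] = field(default=METHOD_LABELS)

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame.from_dict(self.rows, orient="index")
        frame.index.name = "method"
        return frame


def _honest_metrics(y_actual: np.ndarray, y_pred: np.ndarray) -> dict:
    """Regress predicted on actual hold-out values; R² and residual SS."""
    pred_err_ss = float(np.sum((y_pred - y_actual) ** 2))
    if np.ptp(y_pred) <= 1e-12 * max(1.0, float(np.abs(y_pred).max())):
        warnings.warn(
            "degenerate (constant) hold-out predictions; honest R² set to 0",
            UserWarning,
            stacklevel=3,
        )
        return {
            "honest_r2": 0.0,
            "honest_rss": float(np.sum((y_pred - y_pred.mean()) ** 2)),
            "prediction_error_ss": pred_err_ss,
        }
    X = sm.add_constant(y_actual)
    res = sm.OLS(y_pred, X).fit()
    return {
        "honest_r2": float(res.rsquared),
        "honest_rss": float(res.ssr),
        "prediction_error_ss": pred_err_ss,
    }


def honest_validation(
    data: Dataset,
    split: HoldoutSplit,
    fitters: Mapping[str, Callable[[Dataset], FitSummary]],
) -> MethodComparison:
    """Split-sample validation: fit on training cases only, predict the
    hold-out, and score predicted vs actual.

    Each fitter sees a dataset containing *only* the training rows; the
    hold-out rows enter only at prediction time.  Higher honest R² and
    lower honest RSS indicate better out-of-sample performance.
    """
    train = data.subset_rows(split.training)
    X_hold = data.predictors[list(split.holdout)]
    y_hold = data.response[list(split.holdout)]
    rows = {}
    for label, fitter in fitters.items():
        fit = fitter(train)
        y_pred = (
            np.full(len(y_hold), fit.intercept)
            if fit.k == 0
            else predict(fit, X_hold[:, list(fit.subset)])
        )
        rows[label] = {
            "k": fit.k,
            "subset": fit.subset,
            "names": fit.names,
            "adj_r2": fit.adj_r2,
            "aic": fit.aic,
            "p_value": fit.p_value,
            **_honest_metrics(y_hold, y_pred),
        }
    return MethodComparison(rows=rows, holdout=split, labels=tuple(fitters))


def _revs_best(data: Dataset, **revs_kwargs) -> FitSummary:
    return run_revs(data, **revs_kwargs).best_model


def compare_methods(
    data: Dataset,
    holdout: int | None = None,
    seed: int = 0,
    stepwise_direction: str = "forward",
    stepwise_criterion: str = "pvalue",
    alpha: float = 0.05,
    min_drop: float = 2.0,
    **revs_kwargs,
) -> MethodComparison:
    """Benchmark REVS against the full model, stepwise selection and the
    all-subsets comparator.

    All four methods are fitted on the complete data and compared by
    adjusted R², AIC, delta AIC (minimum across methods = 0) and overall P.
    With ``holdout=h`` the 50/40/10-style protocol is added: ``h`` random
    cases are withheld, every method is refitted on the rest, and honest
    R²/RSS are reported per method.
    """

    def stepwise_fitter(d: Dataset) -> FitSummary:
        return stepwise(
            d,
            direction=stepwise_direction,
            criterion=stepwise_criterion,
            alpha=alpha,
            min_drop=min_drop,
        )

    fitters: dict[str, Callable[[Dataset], FitSummary]] = {
        "REVS": lambda d: _revs_best(d, **revs_kwargs),
        "all-subsets": lambda d: best_all_subsets_model(d),
        "stepwise": stepwise_fitter,
        "full": fit_full_model,
    }
    rows = {}
    for label, fitter in fitters.items():
        fit = fitter(data)
        rows[label] = {
            "k": fit.k,
            "subset": fit.subset,
            "names": fit.names,
            "adj_r2": fit.adj_r2,
            "aic": fit.aic,
            "p_value": fit.p_value,
        }
    deltas = delta_aics([rows[label]["aic"] for label in fitters])
    for label, d in zip(fitters, deltas):
        rows[label]["delta_aic"] = float(d)

    split = None
    if holdout is not None:
        split = make_holdout_split(data.n, holdout, seed)
        honest = honest_validation(data, split, fitters)
        for label in fitters:
            for key in ("honest_r2", "honest_rss", "prediction_error_ss"):
                rows[label][key] = honest.rows[label][key]
    return MethodComparison(rows=rows, holdout=split, labels=tuple(fitters))
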