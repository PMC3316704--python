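"""The nested model series built from the empirical variable ranking.

Model 1 contains only the variable with the most empirical support (highest
inclusion count), model 2 adds the next most supported, and so on up to the
full model — ``p`` primary models in total, one per predictor.  The series
is compared in an information-theoretic frame: each model's delta AIC
``Δ_i = AIC_i − AIC_min`` is mapped to a support category, and the lowest
AIC designates the best model (highest adjusted R² and lowest overall P are
reported alongside but do not drive selection by default).

Variables with equal inclusion counts are entered in dataset column order.
That arbitrary order is harmless unless the best model's cutoff falls
*inside* a tie group — some tied variables in, some out — in which case
every alternative same-size choice from the group is fitted as a
tie-alternative model and the best designation is re-made over primaries
and alternatives together, restoring column-order invariance.  Tie groups
wider than five raise by default (wider ties essentially never occur when
the level-best models are exact), with an override that enumerates anyway.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from itertools import combinations
from typing import Sequence

import numpy as np

from .dataset import Dataset
from .linear_model import FitSummary, InsufficientCasesError, fit_subset
from .search import (
    EXHAUSTIVE_THRESHOLD,
    InclusionRanking,
    level_matrix,
    rank_by_inclusion,
)

__all__ = [
    "SupportCategory",
    "SUPPORT_CATEGORIES",
    "TieAlternative",
    "REVSModelSequence",
    "TieWidthError",
    "MAX_TIE_WIDTH",
    "delta_aics",
    "categorize_support",
    "build_nested_sequence",
    "resolve_tie_alternatives",
    "select_best",
    "run_revs",
]

#: Widest tie group resolved by enumeration before raising.
MAX_TIE_WIDTH = 5


class TieWidthError(ValueError):
    """Raised when a tie group wider than :data:`MAX_TIE_WIDTH` must be resolved."""


@dataclass(frozen=True)
class SupportCategory:
    """A delta-AIC band and its plain-language support label."""

    label: str
    lower: float  # exclusive, except 0 which is inclusive
    upper: float  # inclusive

    def contains(self, delta: float) -> bool:
        lo_ok = delta >= self.lower if self.lower == 0 else delta > self.lower
        return lo_ok and delta <= self.upper


#: Δ in [0, 2] = very strong support; (2, 4] = strong; (4, 10] =
#: considerably less; above 10 = essentially none.  The published bands
#: (0–2, 3–4, 5–9, >10) leave gaps at (2, 3), (4, 5) and (9, 10]; they are
#: closed here as contiguous intervals so every Δ gets a category.
SUPPORT_CATEGORIES: tuple[SupportCategory, ...] = (
    SupportCategory("very strong", 0.0, 2.0),
    SupportCategory("strong", 2.0, 4.0),
    SupportCategory("considerably less", 4.0, 10.0),
    SupportCategory("essentially none", 10.0, float("inf")),
)


def delta_aics(aics: Sequence[float]) -> np.ndarray:
    """``Δ_i = AIC_i − AIC_min`` over a set of competing models.

    NaN entries (un-fit or degenerate models) propagate as NaN and are
    ignored when locating the minimum.
    """
    arr = np.asarray(list(aics), dtype=float)
    if arr.size == 0:
        raise ValueError("need at least one AIC value")
    if np.isnan(arr).all():
        raise ValueError("all AIC values are undefined")
    return arr - np.nanmin(arr)


def categorize_support(delta: float) -> SupportCategory:
    """Map a delta AIC to its support category (see :data:`SUPPORT_CATEGORIES`)."""
    if not delta >= 0:
        raise ValueError(f"delta AIC must be non-negative, got {delta}")
    for cat in SUPPORT_CATEGORIES:
        if cat.contains(delta):
            return cat
    raise AssertionError("unreachable: categories partition [0, inf)")


@dataclass(frozen=True)
class TieAlternative:
    """A tie-alternative model: a same-size swap inside one tie group."""

    fit: FitSummary
    tie_group: tuple[int, ...]
    chosen: tuple[int, ...]  # members of the group entered in this variant


@dataclass(frozen=True)
class REVSModelSequence:
    """The ordered nested series plus tie alternatives and designations.

    ``models[j]`` (j = 0..p-1) contains the j+1 highest-ranked variables;
    entries are None where the model could not be fitted (``n <= k + 1``).
    ``best_by_aic`` is either ``("primary", index)`` or
    ``("alternative", index)``.
    """

    models: tuple[FitSummary | None, ...]
    entered: tuple[int, ...]  # variable added at each step, rank order
    entered_signs: tuple[float, ...]  # sign of its slope in that model
    ranking: InclusionRanking
    alternatives: tuple[TieAlternative, ...] = ()
    delta_aic: tuple[float, ...] = ()
    alternative_delta_aic: tuple[float, ...] = ()
    best_by_aic: tuple[str, int] | None = None
    best_by_adj_r2: tuple[str, int] | None = None
    best_by_p: tuple[str, int] | None = None
    competing: tuple[tuple[str, int], ...] = field(default_factory=tuple)

    @property
    def p(self) -> int:
        return len(self.models)

    def model(self, kind: str, index: int) -> FitSummary:
        """Look up a designated model by (kind, index) handle."""
        if kind == "primary":
            fit = self.models[index]
            if fit is None:
                raise ValueError(f"primary model {index} was not fittable")
            return fit
        if kind == "alternative":
            return self.alternatives[index].fit
        raise ValueError(f"unknown model kind {kind!r}")

    @property
    def best_model(self) -> FitSummary:
        """The lowest-AIC model over primaries and tie alternatives."""
        if self.best_by_aic is None:
            raise ValueError("designations not computed yet")
        return self.model(*self.best_by_aic)


def build_nested_sequence(
    data: Dataset, ranking: InclusionRanking
) -> REVSModelSequence:
    """Fit the p cumulative models in empirical-support order.

    Model j holds the top-j ranked variables (ties entered in dataset
    column order, as embedded in ``ranking.order``).  Levels with
    ``n <= k + 1`` are flagged un-fit (None) rather than aborting.  The
    entered variable's coefficient sign is recorded per step so reports can
    state the direction of each relationship.
    """
    if ranking.p != data.p:
        raise ValueError("ranking does not match dataset dimensions")
    models: list[FitSummary | None] = []
    signs: list[float] = []
    for j in range(1, data.p + 1):
        subset = ranking.order[:j]
        try:
            fit = fit_subset(data, subset)
        except InsufficientCasesError:
            models.append(None)
            signs.append(float("nan"))
            continue
        models.append(fit)
        signs.append(float(np.sign(fit.slopes[j - 1])))
    seq = REVSModelSequence(
        models=tuple(models),
        entered=tuple(ranking.order),
        entered_signs=tuple(signs),
        ranking=ranking,
    )
    return _with_deltas_and_designations(seq)


def _aic_of(fit: FitSummary | None) -> float:
    if fit is None:
        return float("nan")
    return fit.aic


def _with_deltas_and_designations(seq: REVSModelSequence) -> REVSModelSequence:
    """Recompute Δ values and best-model designations over all models."""
    primary_aics = [_aic_of(m) for m in seq.models]
    alt_aics = [a.fit.aic for a in seq.alternatives]
    deltas = delta_aics(primary_aics + alt_aics)
    n_primary = len(primary_aics)
    handles: list[tuple[str, int]] = [
        ("primary", i) for i in range(n_primary)
    ] + [("alternative", i) for i in range(len(seq.alternatives))]
    fits: list[FitSummary | None] = list(seq.models) + [
        a.fit for a in seq.alternatives
    ]

    def argbest(key, reverse=False):
        vals = [
            (key(f), h)
            for f, h in zip(fits, handles)
            if f is not None and np.isfinite(key(f))
        ]
        if not vals:
            return None
        # ties go to the earlier (more parsimonious / primary) handle
        target = max(v for v, _ in vals) if reverse else min(v for v, _ in vals)
        for v, h in vals:
            if v == target:
                return h
        return None

    best_aic = argbest(lambda f: f.aic)
    competing = tuple(
        h
        for h, d in zip(handles, deltas)
        if np.isfinite(d) and d <= 2.0
    )
    return replace(
        seq,
        delta_aic=tuple(float(d) for d in deltas[:n_primary]),
        alternative_delta_aic=tuple(float(d) for d in deltas[n_primary:]),
        best_by_aic=best_aic,
        best_by_adj_r2=argbest(lambda f: f.adj_r2, reverse=True),
        best_by_p=argbest(lambda f: f.p_value),
        competing=competing,
    )


def resolve_tie_alternatives(
    seq: REVSModelSequence,
    ranking: InclusionRanking,
    data: Dataset,
    max_tie_width: int = MAX_TIE_WIDTH,
    allow_wide_ties: bool = False,
) -> REVSModelSequence:
    """Fit alternative models wherever a model cutoff splits a tie group.

    A cutoff after ``j`` entries splits a tie group when some tied
    variables are entered and others are not; the default column-order
    entry is then arbitrary, so every alternative same-size selection from
    the group is fitted as a tie-alternative model and the designations are
    re-made over primaries plus alternatives.  Expanding *every* split
    boundary (not only the one at the current AIC optimum) makes the
    candidate model set a function of the inclusion counts alone, which is
    what guarantees that predictor column order cannot change the best
    model.

    Tie groups wider than ``max_tie_width`` are enumerated only when
    ``allow_wide_ties`` is set (with a warning): such groups — typically
    noise variables sharing the minimum count — would explode
    combinatorially, and their members never carry the empirical support a
    best model needs.  If the best model's own cutoff splits a wide group,
    that cannot be ignored and :class:`TieWidthError` is raised instead.
    """
    order = ranking.order

    def split_group_at(j: int):
        """Tie group split by the cutoff after j entries, or None."""
        group = ranking.group_of(order[j - 1])
        n_in = sum(1 for v in group if order.index(v) < j)
        return (group, n_in) if n_in < len(group) else None

    alternatives = list(seq.alternatives)
    skipped_wide: list[int] = []
    for j in range(1, seq.p):
        if seq.models[j - 1] is None:
            continue  # un-fittable level: alternatives would be too
        split = split_group_at(j)
        if split is None:
            continue
        group, n_in = split
        if len(group) > max_tie_width and not allow_wide_ties:
            skipped_wide.append(j)
            continue
        if len(group) > max_tie_width:
            warnings.warn(
                f"enumerating a {len(group)}-way tie at model size {j} "
                f"({2 ** len(group)} candidate selections may be slow)",
                UserWarning,
                stacklevel=2,
            )
        outside = tuple(v for v in order[:j] if v not in group)
        default_choice = tuple(v for v in order[:j] if v in group)
        for chosen in combinations(group, n_in):
            if chosen == default_choice:
                continue  # the primary model itself
            alternatives.append(
                TieAlternative(
                    fit=fit_subset(data, outside + chosen),
                    tie_group=group,
                    chosen=chosen,
                )
            )
    if len(alternatives) > len(seq.alternatives):
        seq = _with_deltas_and_designations(
            replace(seq, alternatives=tuple(alternatives))
        )
    if (
        seq.best_by_aic is not None
        and seq.best_by_aic[0] == "primary"
        and seq.best_by_aic[1] + 1 in skipped_wide
    ):
        width = len(split_group_at(seq.best_by_aic[1] + 1)[0])
        raise TieWidthError(
            f"tie too wide: the best model's cutoff splits a {width}-way "
            f"tie (limit {max_tie_width}); pass allow_wide_ties=True to "
            "enumerate anyway"
        )
    return seq


def select_best(seq: REVSModelSequence) -> dict:
    """Summarise the three designations and the Δ ≤ 2 competing set.

    Lowest AIC is the primary criterion; highest adjusted R² and lowest
    overall P are reported for completeness.
    """
    if seq.best_by_aic is None:
        raise ValueError("sequence has no fitted model")
    return {
        "best_by_aic": seq.best_by_aic,
        "best_by_adj_r2": seq.best_by_adj_r2,
        "best_by_p": seq.best_by_p,
        "competing": seq.competing,
    }


def run_revs(
    data: Dataset,
    exhaustive_threshold: int = EXHAUSTIVE_THRESHOLD,
    max_tie_width: int = MAX_TIE_WIDTH,
    allow_wide_ties: bool = False,
) -> REVSModelSequence:
    """Full pipeline: level-best subsets → inclusion ranking → nested series
    → tie resolution → designations."""
    matrix = level_matrix(data, exhaustive_threshold=exhaustive_threshold)
    ranking = rank_by_inclusion(matrix)
    seq = build_nested_sequence(data, ranking)
    return resolve_tie_alternatives(
        seq, ranking, data,
        max_tie_width=max_tie_width, allow_wide_ties=allow_wide_ties,
    )
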