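"""Exact per-level best-subset search and the inclusion-count ranking.

For every model size ("level") ``k = 1..p`` this module finds the size-k
predictor subset minimising the residual sum of squares — equivalently,
maximising R², since all candidates at a level share the same total sum of
squares.  Two routes return identical answers:

* exhaustive enumeration of all C(p, k) subsets per level, used up to
  ``exhaustive_threshold`` predictors;
* a branch-and-bound search over the subset lattice above it, pruned with
  the monotonicity of least squares (adding predictors never increases the
  RSS, so the RSS of a candidate pool lower-bounds the RSS of every subset
  drawn from it).  Unlike heuristic "pathway" searches, this bound is exact:
  a branch is discarded only when it provably cannot contain a better subset
  at any still-open level, so per-level optimality is guaranteed.

Stacking the level-best subsets as indicator rows gives a p x p boolean
matrix (levels as rows, variables as columns); the column sums are each
variable's *inclusion count* — how many level-best models contain it —
which is the empirical support ranking driving the nested model series.

All subset RSS evaluations run on the centred Gram matrix (X'X, X'y, TSS),
so each candidate costs one small positive-definite solve rather than a
pass over the data.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
from scipy import linalg as sla

from .dataset import Dataset
from .linear_model import FitSummary, InsufficientCasesError, fit_subset

try:  # compiled search; optional, same answers as the Python route
    from ._accel import branch_and_bound as _bb_compiled
except ImportError:  # pragma: no cover - numba not installed
    _bb_compiled = None

__all__ = [
    "EXHAUSTIVE_THRESHOLD",
    "LevelSelectionMatrix",
    "InclusionRanking",
    "count_candidate_models",
    "best_subset_at_level",
    "level_matrix",
    "rank_by_inclusion",
]

#: Up to this many predictors every level is solved by full enumeration;
#: above it the branch-and-bound search takes over (identical answers).
EXHAUSTIVE_THRESHOLD = 15

#: Two subsets whose RSS differ by at most this fraction of max(TSS, 1) are
#: treated as tied; ties are broken by the lexicographically smallest
#: index list.
RSS_TIE_RTOL = 1e-9


def count_candidate_models(p: int) -> int:
    """Number of non-empty predictor subsets, ``2**p - 1``.

    Four predictors give 15 candidate models; thirty give 1,073,741,823 —
    the combinatorial blow-up that makes exhaustive all-subsets comparison
    impractical and motivates ranking variables instead of models.
    """
    if p < 1:
        raise ValueError("p must be at least 1")
    return 2**p - 1


@dataclass(frozen=True)
class LevelSelectionMatrix:
    """Boolean p x p matrix of level-best subsets.

    Row ``k-1`` is the indicator of the best k-variable subset; column sums
    are the inclusion counts.  ``level_rss``/``level_r2`` hold each row's
    residual sum of squares and R².
    """

    matrix: np.ndarray
    level_rss: np.ndarray
    level_r2: np.ndarray
    predictor_names: tuple[str, ...]

    @property
    def p(self) -> int:
        return self.matrix.shape[0]

    def subset_at_level(self, k: int) -> tuple[int, ...]:
        """Predictor indices of the best size-``k`` subset (1-based level)."""
        if not 1 <= k <= self.p:
            raise ValueError(f"level {k} out of range 1..{self.p}")
        return tuple(int(i) for i in np.flatnonzero(self.matrix[k - 1]))

    def to_frame(self):
        """TRUE/FALSE table, variables as columns and levels as rows."""
        import pandas as pd

        return pd.DataFrame(
            self.matrix,
            index=[f"level_{k}" for k in range(1, self.p + 1)],
            columns=list(self.predictor_names),
        )


@dataclass(frozen=True)
class InclusionRanking:
    """Per-variable inclusion counts and the derived entry order.

    ``order`` sorts variables by descending count; variables with equal
    counts form a tie group and keep their original dataset column order
    both inside ``order`` and inside ``tie_groups``.
    """

    counts: np.ndarray
    order: tuple[int, ...]
    tie_groups: tuple[tuple[int, ...], ...]
    predictor_names: tuple[str, ...]

    @property
    def p(self) -> int:
        return len(self.order)

    def group_of(self, var: int) -> tuple[int, ...]:
        """The tie group containing ``var`` (singleton if untied)."""
        for group in self.tie_groups:
            if var in group:
                return group
        raise KeyError(var)


# ---------------------------------------------------------------------------
# Gram-matrix RSS kernel


class _GramKernel:
    """Centred cross-product matrices for O(k^3) subset RSS evaluation."""

    def __init__(self, data: Dataset):
        X = data.predictors - data.predictors.mean(axis=0)
        y = data.response - data.response.mean()
        self.G = X.T @ X
        self.g = X.T @ y
        self.tss = float(y @ y)
        self.p = data.p
        self.tol = RSS_TIE_RTOL * max(self.tss, 1.0)

    def rss(self, subset: Sequence[int]) -> float:
        """RSS of the least-squares fit on ``subset`` (with intercept)."""
        idx = list(subset)
        if not idx:
            return self.tss
        G = self.G[np.ix_(idx, idx)]
        g = self.g[idx]
        try:
            c, low = sla.cho_factor(G, check_finite=False)
            b = sla.cho_solve((c, low), g, check_finite=False)
        except (np.linalg.LinAlgError, sla.LinAlgError):
            b, *_ = np.linalg.lstsq(G, g, rcond=None)
        return max(self.tss - float(g @ b), 0.0)


def _better(rss: float, subset: tuple[int, ...],
            best_rss: float, best_subset, tol: float) -> bool:
    """Strictly smaller RSS wins; near-ties go to the smaller index list."""
    if rss < best_rss - tol:
        return True
    if rss <= best_rss + tol and (best_subset is None or subset < best_subset):
        return True
    return False


def _search_exhaustive(kern: _GramKernel) -> tuple[list, np.ndarray]:
    p = kern.p
    best_subset: list = [None] * (p + 1)
    best_rss = np.full(p + 1, np.inf)
    for k in range(1, p + 1):
        # lexicographic enumeration order makes "keep first" the tie rule
        for comb in combinations(range(p), k):
            rss = kern.rss(comb)
            if rss < best_rss[k] - kern.tol:
                best_rss[k] = rss
                best_subset[k] = comb
    return best_subset, best_rss


def _search_branch_and_bound(kern: _GramKernel) -> tuple[list, np.ndarray]:
    """Exact all-levels best-subset search with RSS-bound pruning.

    Nodes are (committed C, pool B) pairs with C ⊆ B; the node's bound set B
    is itself a candidate at level |B|, and RSS(B) lower-bounds every subset
    S with C ⊆ S ⊆ B, so a node is pruned when RSS(B) cannot improve (or
    tie) the incumbent at any level in [|C|, |B|].
    """
    p = kern.p
    tol = kern.tol
    best_subset: list = [None] * (p + 1)
    best_rss = np.full(p + 1, np.inf)

    def consider(subset: tuple[int, ...], rss: float) -> None:
        k = len(subset)
        if _better(rss, subset, best_rss[k], best_subset[k], tol):
            best_rss[k] = min(rss, best_rss[k])
            best_subset[k] = subset

    # seed incumbents with greedy forward selection: cheap, and tight
    # incumbents make the bound bite early
    chosen: list[int] = []
    remaining = list(range(p))
    while remaining:
        rss_next = [(kern.rss(chosen + [j]), j) for j in remaining]
        best_next = min(rss_next)
        chosen.append(best_next[1])
        remaining.remove(best_next[1])
        consider(tuple(sorted(chosen)), best_next[0])

    # greedy backward elimination seeds the mid/high levels the forward
    # pass may have missed
    pool = list(range(p))
    while len(pool) > 1:
        scored = [(kern.rss([v for v in pool if v != x]), x) for x in pool]
        drop_rss, drop = min(scored)
        pool.remove(drop)
        consider(tuple(sorted(pool)), drop_rss)

    def expand(pool: tuple[int, ...], committed: tuple[int, ...],
               pool_rss: float) -> None:
        free = [v for v in pool if v not in set(committed)]
        hi = len(pool) - 1
        lo0 = max(len(committed), 1)
        children = []
        for x in free:
            child_pool = tuple(v for v in pool if v != x)
            lo = lo0
            if np.all(pool_rss > best_rss[lo : hi + 1] + tol):
                return  # incumbents improved enough to kill all remaining
            child_rss = kern.rss(child_pool)
            if np.all(child_rss > best_rss[lo : hi + 1] + tol):
                continue
            consider(child_pool, child_rss)
            children.append((child_rss, x, child_pool))
        # explore the least harmful deletion first, committing earlier-
        # tried variables in later children; strong small-model incumbents
        # found early make the bound bite everywhere else
        children.sort(key=lambda c: c[0])
        committed_now: list[int] = list(committed)
        for child_rss, x, child_pool in children:
            lo = max(len(committed_now), 1)
            hi_c = len(child_pool)
            if hi_c > lo and not np.all(
                child_rss > best_rss[lo : hi_c + 1] + tol
            ):
                expand(child_pool, tuple(committed_now), child_rss)
            committed_now.append(x)

    full = tuple(range(p))
    full_rss = kern.rss(full)
    consider(full, full_rss)
    expand(full, (), full_rss)
    return best_subset, best_rss


def level_matrix(
    data: Dataset, exhaustive_threshold: int = EXHAUSTIVE_THRESHOLD
) -> LevelSelectionMatrix:
    """Best subset at every level, as a boolean level x variable matrix.

    Enumerates exhaustively for ``p <= exhaustive_threshold`` and switches
    to branch-and-bound above (pass 0 to force branch-and-bound); the two
    routes are exact and interchangeable.

    Raises
    ------
    InsufficientCasesError
        If ``n <= p + 1`` so the top level cannot be fitted.
    """
    p, n = data.p, data.n
    if n <= p + 1:
        raise InsufficientCasesError(
            f"insufficient cases: n={n} <= p+1={p + 1}"
        )
    kern = _GramKernel(data)
    if p <= exhaustive_threshold:
        best_subset, best_rss = _search_exhaustive(kern)
    elif _bb_compiled is not None:
        best_subset, best_rss = _bb_compiled(kern.G, kern.g, kern.tss, kern.tol)
    else:
        best_subset, best_rss = _search_branch_and_bound(kern)
    matrix = np.zeros((p, p), dtype=bool)
    for k in range(1, p + 1):
        matrix[k - 1, list(best_subset[k])] = True
    rss = np.asarray(best_rss[1:], dtype=float)
    r2 = 1.0 - rss / kern.tss if kern.tss > 0 else np.zeros(p)
    return LevelSelectionMatrix(matrix, rss, r2, data.predictor_names)


def best_subset_at_level(
    data: Dataset,
    k: int,
    exhaustive_threshold: int = EXHAUSTIVE_THRESHOLD,
) -> tuple[tuple[int, ...], FitSummary]:
    """The size-``k`` subset with minimal RSS, plus its full fit summary."""
    if not 1 <= k <= data.p:
        raise ValueError(f"level {k} out of range 1..{data.p}")
    if data.n <= k + 1:
        raise InsufficientCasesError(
            f"insufficient cases: n={data.n} <= k+1={k + 1}"
        )
    kern = _GramKernel(data)
    if data.p <= exhaustive_threshold:
        best: tuple[int, ...] | None = None
        best_rss = np.inf
        for comb in combinations(range(data.p), k):
            rss = kern.rss(comb)
            if rss < best_rss - kern.tol:
                best_rss, best = rss, comb
    elif _bb_compiled is not None:
        subsets, _ = _bb_compiled(kern.G, kern.g, kern.tss, kern.tol)
        best = subsets[k]
    else:
        subsets, _ = _search_branch_and_bound(kern)
        best = subsets[k]
    assert best is not None
    return best, fit_subset(data, best)


def rank_by_inclusion(m: LevelSelectionMatrix) -> InclusionRanking:
    """Inclusion counts, descending-count order and tie groups.

    A variable included in 20 of 25 level-best models gets count 20; counts
    run from 1 (entering only the full model) to p (entering every level).
    Variables with equal counts form a tie group and keep their dataset
    column order.
    """
    mat = np.asarray(m.matrix, dtype=bool)
    p = mat.shape[0]
    row_sums = mat.sum(axis=1)
    if mat.shape != (p, p) or not np.array_equal(row_sums, np.arange(1, p + 1)):
        raise ValueError(
            "malformed level matrix: row k must contain exactly k TRUE values"
        )
    counts = mat.sum(axis=0)
    # stable sort on -count keeps dataset column order within equal counts
    order = tuple(int(i) for i in np.argsort(-counts, kind="stable"))
    groups: list[tuple[int, ...]] = []
    start = 0
    while start < p:
        stop = start
        while stop < p and counts[order[stop]] == counts[order[start]]:
            stop += 1
        groups.append(tuple(order[start:stop]))
        start = stop
    return InclusionRanking(
        counts=counts.astype(int),
        order=order,
        tie_groups=tuple(groups),
        predictor_names=m.predictor_names,
    )
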