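"""Shared fixtures and independent oracles.

The brute-force oracle deliberately avoids the package's Gram-matrix
kernel: every subset is fitted through ``numpy.linalg.lstsq`` on the raw
design matrix (with an explicit intercept column), so agreement between
the search module and the oracle checks two independent numerical routes.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pytest

from revs import Dataset, SyntheticSpec, generate_synthetic


def lstsq_rss(data: Dataset, subset) -> float:
    """RSS of the least-squares fit on ``subset``, via the raw design."""
    X = np.column_stack(
        [np.ones(data.n), data.predictors[:, list(subset)]]
    )
    resid = data.response - X @ np.linalg.lstsq(X, data.response, rcond=None)[0]
    return float(resid @ resid)


def oracle_best_subsets(data: Dataset) -> dict[int, tuple[tuple[int, ...], float]]:
    """Exhaustive per-level argmin-RSS subsets, lexicographic tie rule."""
    out = {}
    tol = 1e-9 * max(
        float(np.sum((data.response - data.response.mean()) ** 2)), 1.0
    )
    for k in range(1, data.p + 1):
        best, best_rss = None, np.inf
        for comb in combinations(range(data.p), k):
            rss = lstsq_rss(data, comb)
            if rss < best_rss - tol:
                best, best_rss = comb, rss
        out[k] = (best, best_rss)
    return out


@pytest.fixture
def small_data() -> Dataset:
    """Seeded n=60, p=8 correlated dataset with three true effects."""
    return generate_synthetic(
        SyntheticSpec(
            n=60, p=8, effects={0: 1.0, 2: 0.8, 5: 1.2}, rho=0.5, seed=7
        )
    )


@pytest.fixture
def medium_data() -> Dataset:
    """Seeded n=80, p=6 dataset used for ranking/sequence composition."""
    return generate_synthetic(
        SyntheticSpec(n=80, p=6, effects={1: 1.0, 4: 0.7}, rho=0.4, seed=11)
    )


@pytest.fixture
def exact_line_data() -> Dataset:
    """y = 2*x1 + 1 exactly, plus an irrelevant second predictor."""
    x1 = np.arange(1.0, 7.0)
    x2 = np.array([3.0, 1.0, 4.0, 1.0, 5.0, 9.0])
    return Dataset(2 * x1 + 1, np.column_stack([x1, x2]), ("x1", "x2"))
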