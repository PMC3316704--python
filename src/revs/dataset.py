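"""Rectangular regression datasets: container, CSV ingestion and a seeded
synthetic generator.

A :class:`Dataset` holds one numeric response vector ``y`` and an ``n x p``
predictor matrix, the shape every other module consumes.  CSV files are read
with a header row; every numeric column other than the named response becomes
a predictor.  The synthetic generator emulates the structure of ecological
species–habitat tables: moderate ``n``, many mutually correlated predictors
(AR(1) or equicorrelated multivariate normal), a small set of true nonzero
effects and Gaussian noise — plus optional near-duplicate "tie-inducing"
columns that create exactly the inclusion-count ties the tie-resolution
machinery exists for.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_PREDICTOR_CAP",
    "Dataset",
    "SyntheticSpec",
    "read_dataset",
    "write_dataset_csv",
    "generate_synthetic",
]

logger = logging.getLogger(__name__)

#: Default maximum number of predictor columns (32 total variable columns:
#: 31 predictors and 1 response).  Not intrinsic to the algorithm; callers
#: may override it everywhere it is enforced.
DEFAULT_PREDICTOR_CAP = 31


class DatasetError(ValueError):
    """Raised when a dataset violates its structural invariants."""


@dataclass(frozen=True)
class Dataset:
    """One response vector plus an ``n x p`` predictor matrix.

    Parameters
    ----------
    response : ndarray, shape (n,)
        The dependent variable ``y``.
    predictors : ndarray, shape (n, p)
        Predictor columns ``x_1 .. x_p``.
    predictor_names : tuple of str
        Unique labels, one per predictor column.
    response_name : str
        Label of the response column.
    """

    response: np.ndarray
    predictors: np.ndarray
    predictor_names: tuple[str, ...] = ()
    response_name: str = "y"

    def __post_init__(self) -> None:
        y = np.asarray(self.response, dtype=float)
        X = np.asarray(self.predictors, dtype=float)
        if X.ndim != 2:
            raise DatasetError("predictors must be a 2-D matrix")
        if y.ndim != 1 or y.shape[0] != X.shape[0]:
            raise DatasetError("response length must match predictor rows")
        n, p = X.shape
        if n < 3:
            raise DatasetError(f"need at least 3 cases, got {n}")
        if p < 1:
            raise DatasetError("need at least one predictor")
        if not (np.isfinite(y).all() and np.isfinite(X).all()):
            raise DatasetError("dataset contains missing or non-finite values")
        names = tuple(self.predictor_names) or tuple(
            f"x{i + 1}" for i in range(p)
        )
        if len(names) != p:
            raise DatasetError("one name per predictor column required")
        if len(set(names)) != p or self.response_name in names:
            raise DatasetError("variable names must be unique")
        object.__setattr__(self, "response", y)
        object.__setattr__(self, "predictors", X)
        object.__setattr__(self, "predictor_names", names)

    @property
    def n(self) -> int:
        """Number of cases."""
        return self.predictors.shape[0]

    @property
    def p(self) -> int:
        """Number of predictors."""
        return self.predictors.shape[1]

    def subset_rows(self, rows: Sequence[int]) -> "Dataset":
        """Return the dataset restricted to the given case indices."""
        rows = np.asarray(rows, dtype=int)
        return Dataset(
            self.response[rows],
            self.predictors[rows],
            self.predictor_names,
            self.response_name,
        )

    def permute_columns(self, order: Sequence[int]) -> "Dataset":
        """Return a dataset with predictor columns reordered by ``order``."""
        order = list(order)
        if sorted(order) != list(range(self.p)):
            raise DatasetError("order must be a permutation of column indices")
        return Dataset(
            self.response,
            self.predictors[:, order],
            tuple(self.predictor_names[i] for i in order),
            self.response_name,
        )

    def to_frame(self) -> pd.DataFrame:
        """Response + predictors as a DataFrame (response column first)."""
        frame = pd.DataFrame(self.predictors, columns=list(self.predictor_names))
        frame.insert(0, self.response_name, self.response)
        return frame


def read_dataset(
    path,
    response: str,
    cap: int = DEFAULT_PREDICTOR_CAP,
) -> Dataset:
    """Read a header-row CSV into a :class:`Dataset`.

    All columns other than ``response`` become predictors.  Rows containing
    any missing value are dropped with a logged count.

    Raises
    ------
    DatasetError
        If the response column is absent, a predictor column is non-numeric,
        or the predictor count exceeds ``cap``.
    """
    frame = pd.read_csv(path, float_precision="round_trip")
    if response not in frame.columns:
        raise DatasetError(
            f"response column {response!r} not found in {list(frame.columns)}"
        )
    n_raw = len(frame)
    frame = frame.dropna(axis=0, how="any")
    dropped = n_raw - len(frame)
    if dropped:
        logger.warning("dropped %d row(s) with missing values", dropped)
    predictor_cols = [c for c in frame.columns if c != response]
    if len(predictor_cols) > cap:
        raise DatasetError(
            f"{len(predictor_cols)} predictors exceed the cap of {cap} "
            f"({cap} predictors and 1 dependent variable, "
            f"{cap + 1} variable columns in total)"
        )
    for col in predictor_cols:
        if not pd.api.types.is_numeric_dtype(frame[col]):
            raise DatasetError(f"predictor column {col!r} is not numeric")
    if not pd.api.types.is_numeric_dtype(frame[response]):
        raise DatasetError(f"response column {response!r} is not numeric")
    return Dataset(
        frame[response].to_numpy(dtype=float),
        frame[predictor_cols].to_numpy(dtype=float),
        tuple(predictor_cols),
        response,
    )


def write_dataset_csv(data: Dataset, path) -> None:
    """Write a dataset as CSV with full float precision (round-trip safe)."""
    data.to_frame().to_csv(path, index=False, float_format="%.17g")


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for a seeded synthetic dataset.

    Predictors are drawn from a zero-mean multivariate normal whose
    correlation is either AR(1) (``corr[i, j] = rho**|i-j|``) or
    equicorrelated (``rho`` off the diagonal); the response is
    ``X @ beta + Normal(0, sigma)``.  ``duplicates`` appends extra columns
    that copy an existing column plus independent ``Normal(0, jitter)``
    noise, which reliably produces inclusion-count ties while keeping the
    design full-rank for ``jitter > 0``.

    Parameters
    ----------
    n, p : int
        Cases and base predictors.
    effects : mapping of column index to slope
        The true nonzero coefficients; all other slopes are zero.
    correlation : {"ar1", "equicorrelation"}
    rho : float
        Correlation parameter, ``|rho| < 1``.
    sigma : float
        Noise standard deviation, ``> 0``.
    duplicates : tuple of (source index, jitter sd)
        Tie-inducing near-duplicate columns appended after the base ones.
    seed : int
    """

    n: int
    p: int
    effects: Mapping[int, float] = field(default_factory=dict)
    correlation: str = "ar1"
    rho: float = 0.5
    sigma: float = 1.0
    duplicates: tuple[tuple[int, float], ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if not abs(self.rho) < 1:
            raise DatasetError("|rho| must be < 1")
        if not self.sigma > 0:
            raise DatasetError("sigma must be positive")
        if self.correlation not in ("ar1", "equicorrelation"):
            raise DatasetError(f"unknown correlation {self.correlation!r}")
        if any(not np.isfinite(b) for b in self.effects.values()):
            raise DatasetError("effects must be finite")
        if any(not 0 <= j < self.p for j in self.effects):
            raise DatasetError("effect indices out of range")


def _correlation_matrix(spec: SyntheticSpec) -> np.ndarray:
    idx = np.arange(spec.p)
    if spec.correlation == "ar1":
        return spec.rho ** np.abs(idx[:, None] - idx[None, :])
    corr = np.full((spec.p, spec.p), spec.rho)
    np.fill_diagonal(corr, 1.0)
    return corr


def generate_synthetic(spec: SyntheticSpec) -> Dataset:
    """Draw a reproducible synthetic dataset from ``spec``.

    Raises
    ------
    DatasetError
        If the implied correlation matrix is not positive definite (e.g.
        equicorrelation with ``rho < -1/(p-1)``).
    """
    rng = np.random.default_rng(spec.seed)
    corr = _correlation_matrix(spec)
    try:
        chol = np.linalg.cholesky(corr)
    except np.linalg.LinAlgError as exc:
        raise DatasetError(
            "correlation matrix is not positive definite"
        ) from exc
    X = rng.standard_normal((spec.n, spec.p)) @ chol.T
    beta = np.zeros(spec.p)
    for j, b in spec.effects.items():
        beta[j] = b
    y = X @ beta + spec.sigma * rng.standard_normal(spec.n)

    names = [f"x{i + 1}" for i in range(spec.p)]
    if spec.duplicates:
        extra = []
        for src, jitter in spec.duplicates:
            col = X[:, src] + jitter * rng.standard_normal(spec.n)
            extra.append(col)
            names.append(f"x{src + 1}_dup{sum(1 for c in names if c.startswith(f'x{src + 1}_dup')) + 1}")
        X = np.column_stack([X] + extra)
    return Dataset(y, X, tuple(names), "y")
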