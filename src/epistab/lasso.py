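"""L1-penalized logistic path, cross-validated penalty choice, and the
dummy-column coding used to map penalized coefficients back to variables.

The penalty is parameterized as in the coordinate-descent literature:

    (1/n) * binomial_nll(beta0, beta) + lambda * ||beta||_1

on columns standardized to unit variance with an unpenalized intercept, so
the smallest all-zero penalty is ``lambda_max = max_j |x_j^T (y - ybar)|/n``.

A variable counts as *selected* at a given penalty if at least one of its
non-MISSING dummy columns carries a nonzero coefficient; a variable whose
only nonzero dummy is its explicit MISSING level is not selected (missing
response categories carry no substantive association).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _solver
from .errors import DegenerateDataError, SchemaError
from .preprocess import MISSING

__all__ = [
    "DesignCoding",
    "CVResult",
    "encode_candidates",
    "standardize",
    "lambda_max",
    "lambda_grid",
    "fit_lasso_path",
    "select_lambda_min",
    "variable_selected_at",
    "stratified_fold_ids",
]


@dataclass(frozen=True)
class ColumnInfo:
    """One design-matrix column: its source variable, the categorical level
    it encodes (None for continuous), and whether that level is MISSING."""

    variable: str
    level: str | None
    is_missing_level: bool


@dataclass
class DesignCoding:
    """Dummy coding of a set of candidate variables.

    Categorical variables are reference-coded against their first observed
    non-MISSING level; the MISSING level, when present, always receives its
    own dummy so selection can ignore it.  Continuous variables map to a
    single column.
    """

    columns: list[ColumnInfo] = field(default_factory=list)

    @property
    def n_columns(self) -> int:
        return len(self.columns)

    def variables(self) -> list[str]:
        seen: dict[str, None] = {}
        for c in self.columns:
            seen.setdefault(c.variable, None)
        return list(seen)


def encode_candidates(
    df: pd.DataFrame, candidates: list[str]
) -> tuple[np.ndarray, DesignCoding]:
    """One-hot encode candidate variables into a dense (n, p) float matrix.

    Numeric columns pass through unchanged; categorical columns are
    reference-coded (first observed non-MISSING level is the reference).
    """
    cols: list[np.ndarray] = []
    info: list[ColumnInfo] = []
    n = len(df)
    for var in candidates:
        if var not in df.columns:
            raise SchemaError(f"candidate column {var!r} absent from table")
        s = df[var]
        if pd.api.types.is_numeric_dtype(s):
            cols.append(s.to_numpy(dtype=float))
            info.append(ColumnInfo(var, None, False))
            continue
        values = s.astype(str).to_numpy()
        levels = list(pd.unique(values))
        non_missing = [lv for lv in levels if lv != MISSING]
        if not non_missing:
            raise SchemaError(f"column {var!r} is entirely MISSING")
        reference = non_missing[0]
        for lv in levels:
            if lv == reference:
                continue
            cols.append((values == lv).astype(float))
            info.append(ColumnInfo(var, lv, lv == MISSING))
    X = (
        np.column_stack(cols) if cols else np.empty((n, 0), dtype=float)
    )
    return X, DesignCoding(info)


def standardize(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Center columns and scale to unit (population) variance.

    Returns the standardized matrix restricted to non-degenerate columns
    and a boolean mask of the columns kept (zero-variance columns are
    dropped).
    """
    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    keep = sd > 0
    Xs = (X[:, keep] - mean[keep]) / sd[keep]
    return Xs, keep


def lambda_max(X: np.ndarray, y: np.ndarray) -> float:
    """Smallest penalty with an all-zero solution (KKT bound) for centered,
    standardized columns: ``max_j |x_j^T (y - ybar)| / n``."""
    n = X.shape[0]
    resid = y - y.mean()
    return float(np.abs(X.T @ resid).max() / n)


def lambda_grid(
    lam_max: float, n_lambda: int = 100, min_ratio: float = 1e-4
) -> np.ndarray:
    """Log-spaced decreasing penalty grid from ``lam_max`` down to
    ``lam_max * min_ratio``."""
    return lam_max * np.logspace(0.0, np.log10(min_ratio), n_lambda)


def fit_lasso_path(
    X: np.ndarray,
    y: np.ndarray,
    lambdas: np.ndarray,
    *,
    tol: float = 1e-7,
    max_outer: int = 30,
    dev_change_tol: float = 0.0,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Penalized path over a decreasing grid on an already-standardized X.

    Returns ``(betas, intercepts, n_computed)`` where ``betas`` has one row
    per grid penalty (rows beyond ``n_computed`` are zero if the path
    terminated early).  A constant response yields an all-zero path with a
    warning.
    """
    y = np.asarray(y, dtype=float)
    if y.min() == y.max():
        warnings.warn(
            "response is constant; returning an all-zero penalized path",
            stacklevel=2,
        )
        return (
            np.zeros((len(lambdas), X.shape[1])),
            np.zeros(len(lambdas)),
            len(lambdas),
        )
    XT = np.ascontiguousarray(X.T)
    betas, b0s, ncomp = _solver.fit_logistic_path(
        XT, y, np.asarray(lambdas, dtype=float), tol, max_outer,
        dev_change_tol,
    )
    return betas, b0s, int(ncomp)


def stratified_fold_ids(
    y: np.ndarray, n_folds: int, rng: np.random.Generator
) -> np.ndarray:
    """Fold labels stratified on the binary response so every fold sees
    both classes (provided each class has at least ``n_folds`` members
    spread round-robin)."""
    fold = np.empty(len(y), dtype=np.int64)
    for cls in (0, 1):
        idx = np.flatnonzero(y == cls)
        idx = rng.permutation(idx)
        fold[idx] = np.arange(len(idx)) % n_folds
    return fold


@dataclass
class CVResult:
    """Cross-validation summary for one penalized path.

    ``cv_se`` is the fold-to-fold standard error of the mean CV error per
    penalty (the quantity behind one-standard-error reasoning).
    """

    lambda_grid: np.ndarray
    mean_cv_error: np.ndarray
    cv_se: np.ndarray
    lambda_min: float
    lambda_min_index: int


def select_lambda_min(
    X: np.ndarray,
    y: np.ndarray,
    *,
    n_folds: int = 10,
    rng: np.random.Generator | None = None,
    lambdas: np.ndarray | None = None,
    n_lambda: int = 100,
    min_ratio: float = 1e-4,
    cv_tol: float = 1e-4,
    cv_max_outer: int = 1,
    dev_change_tol: float = 1e-5,
) -> CVResult:
    """Pick the penalty minimizing mean held-out binomial deviance.

    ``X`` must already be standardized.  Folds are stratified on ``y``; CV
    path fits use the fast single-quadratic-approximation mode of the
    solver.  Ties in CV error resolve toward the larger penalty (the
    sparser model).
    """
    y = np.asarray(y, dtype=float)
    if y.min() == y.max():
        raise DegenerateDataError(
            "cannot cross-validate: a response class is absent"
        )
    if rng is None:
        rng = np.random.default_rng()
    if lambdas is None:
        lambdas = lambda_grid(lambda_max(X, y), n_lambda, min_ratio)
    fold_ids = stratified_fold_ids(y, n_folds, rng)
    XT = np.ascontiguousarray(X.T)
    fold_tot, fold_counts = _solver.cv_deviance(
        XT, y, np.asarray(lambdas, dtype=float), fold_ids, n_folds,
        cv_tol, cv_max_outer, dev_change_tol,
    )
    cv_err = fold_tot.sum(axis=0) / len(y)
    fold_means = fold_tot / fold_counts[:, None]
    cv_se = fold_means.std(axis=0, ddof=1) / np.sqrt(n_folds)
    # argmin returns the first (largest-lambda) minimizer: sparser on ties
    imin = int(np.argmin(cv_err))
    return CVResult(
        lambda_grid=np.asarray(lambdas),
        mean_cv_error=cv_err,
        cv_se=cv_se,
        lambda_min=float(lambdas[imin]),
        lambda_min_index=imin,
    )


def variable_selected_at(
    coefficients: np.ndarray,
    coding: DesignCoding,
    keep_mask: np.ndarray | None = None,
) -> dict[str, bool]:
    """Map penalized coefficients back to per-variable selection flags.

    A variable is selected iff at least one of its non-MISSING columns has
    a nonzero coefficient; columns dropped as zero-variance (``keep_mask``
    False) count as zero.
    """
    if keep_mask is None:
        keep_mask = np.ones(coding.n_columns, dtype=bool)
    if keep_mask.sum() != len(coefficients):
        raise SchemaError(
            "coefficient vector does not match the coding's kept columns"
        )
    selected = {v: False for v in coding.variables()}
    k = 0
    for j, colinfo in enumerate(coding.columns):
        if not keep_mask[j]:
            continue
        if coefficients[k] != 0.0 and not colinfo.is_missing_level:
            selected[colinfo.variable] = True
        k += 1
    return selected
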