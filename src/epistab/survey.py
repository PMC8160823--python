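"""Design-based weighted logistic regression and survey descriptives.

Point estimates solve the weighted score equations

    sum_i w_i x_i (y_i - p_i(beta)) = 0

by iteratively reweighted least squares.  The covariance is the Taylor
linearization (sandwich) estimator used for stratified multistage samples
analyzed with replacement: the bread is the inverse weighted information,
the meat the between-PSU covariance of stratum-centered PSU totals of the
score residuals, with stratum factors n_h / (n_h - 1).  A stratum left
with a single PSU (which subgroup analyses can produce) contributes its
PSU total centered at the grand mean — a conservative lonely-PSU
adjustment.  Design degrees of freedom are (#PSUs - #strata).

Collinearity is screened with generalized variance-inflation factors on
the weighted predictor correlation matrix:

    GVIF(term) = det(R_term) det(R_others) / det(R_all)

reported as GVIF^(1/(2 df)) and flagged above 1.4.

Weighted prevalences use the ratio estimator with the same linearized
variance machinery.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import (
    ConfigurationError,
    ConvergenceError,
    DegenerateDataError,
    SchemaError,
    SeparationError,
)
from .preprocess import MISSING, RespondentTable

__all__ = ["ModelSpec", "FitResult", "fit_survey_logistic", "compute_gvif",
           "weighted_prevalence"]

logger = logging.getLogger(__name__)

GVIF_THRESHOLD = 1.4


@dataclass(frozen=True)
class ModelSpec:
    """Outcome, exposure, and adjustment variables for one model.

    Model 1 adjusts for the forced demographics only; Model 2 adds the
    confounders identified by stability selection.
    """

    outcome: str
    exposure: str
    adjustment: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.exposure in self.adjustment:
            raise ConfigurationError("exposure cannot appear in adjustment")


@dataclass
class FitResult:
    """A fitted design-weighted logistic model."""

    column_names: list[str]
    beta: np.ndarray
    vcov: np.ndarray
    n: int
    df_design: int
    gvif_table: pd.DataFrame
    n_iterations: int

    def coef(self, name: str) -> tuple[float, float]:
        """(log-odds, SE) for one design-matrix column."""
        j = self.column_names.index(name)
        return float(self.beta[j]), float(np.sqrt(self.vcov[j, j]))


def _model_matrix(
    df: pd.DataFrame, spec: ModelSpec
) -> tuple[np.ndarray, list[str], list[tuple[str, list[int]]]]:
    """Intercept + exposure + reference-coded adjustment terms.

    Returns the matrix, column names, and per-term column groupings
    (exposure and each adjustment variable are single terms).
    """
    n = len(df)
    cols: list[np.ndarray] = [np.ones(n)]
    names = ["(intercept)"]
    groups: list[tuple[str, list[int]]] = []

    def add_variable(var: str) -> None:
        s = df[var]
        start = len(cols)
        if pd.api.types.is_numeric_dtype(s):
            cols.append(s.to_numpy(dtype=float))
            names.append(var)
        else:
            vals = s.astype(str).to_numpy()
            levels = list(pd.unique(vals))
            non_missing = [lv for lv in levels if lv != MISSING]
            if not non_missing:
                raise SchemaError(f"column {var!r} is entirely MISSING")
            reference = non_missing[0]
            for lv in levels:
                if lv == reference:
                    continue
                cols.append((vals == lv).astype(float))
                names.append(f"{var}[{lv}]")
        idx = list(range(start, len(cols)))
        if not idx:
            raise DegenerateDataError(f"variable {var!r} is constant")
        groups.append((var, idx))

    add_variable(spec.exposure)
    for var in spec.adjustment:
        add_variable(var)
    return np.column_stack(cols), names, groups


def _psu_totals(
    scores: np.ndarray, stratum: np.ndarray, psu: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Sum score rows within (stratum, PSU); returns totals and the stratum
    index of each PSU."""
    key = np.char.add(
        np.char.add(stratum.astype(str), "\x1f"), psu.astype(str)
    )
    codes, _ = pd.factorize(key)
    n_psu = codes.max() + 1
    p = scores.shape[1]
    totals = np.zeros((n_psu, p))
    np.add.at(totals, codes, scores)
    # stratum of each PSU, from the first record seen in that PSU
    seen = np.full(n_psu, -1, dtype=int)
    for i, c in enumerate(codes):
        if seen[c] < 0:
            seen[c] = i
    strat_codes, _ = pd.factorize(stratum.astype(str))
    return totals, strat_codes[seen]


def _linearized_meat(
    scores: np.ndarray, stratum: np.ndarray, psu: np.ndarray
) -> tuple[np.ndarray, int]:
    """Between-PSU covariance of stratum-centered PSU score totals.

    Returns the meat matrix and the design degrees of freedom
    (#PSUs - #strata, floored at 1).
    """
    totals, strat_of_psu = _psu_totals(scores, stratum, psu)
    n_psu, p = totals.shape
    n_strata = strat_of_psu.max() + 1
    meat = np.zeros((p, p))
    grand = totals.mean(axis=0)
    lonely = False
    for h in range(n_strata):
        z = totals[strat_of_psu == h]
        n_h = z.shape[0]
        if n_h == 1:
            # lonely PSU: center at the grand mean of all PSU totals
            d = z[0] - grand
            meat += np.outer(d, d)
            lonely = True
        else:
            d = z - z.mean(axis=0)
            meat += (n_h / (n_h - 1)) * d.T @ d
    if lonely:
        logger.warning(
            "lonely PSU encountered; centering singleton strata at the "
            "grand mean"
        )
    df_design = max(1, n_psu - n_strata)
    return meat, df_design


def compute_gvif(
    X: np.ndarray,
    weights: np.ndarray,
    groups: list[tuple[str, list[int]]],
    names: list[str],
) -> pd.DataFrame:
    """Generalized variance-inflation factors from the weighted predictor
    correlation matrix (intercept excluded by passing predictor columns
    only).

    Each row reports GVIF, the term's column count df, GVIF^(1/(2 df)),
    and whether that exceeds the 1.4 collinearity flag.
    """
    w = weights / weights.sum()
    mu = w @ X
    Xc = X - mu
    cov = Xc.T @ (Xc * w[:, None])
    sd = np.sqrt(np.diag(cov))
    if np.any(sd <= 0):
        bad = [names[j] for j in np.flatnonzero(sd <= 0)]
        raise DegenerateDataError(f"constant predictor column(s): {bad}")
    R = cov / np.outer(sd, sd)
    sign, logdet_all = np.linalg.slogdet(R)
    if sign <= 0:
        raise DegenerateDataError(
            "singular predictor correlation matrix; aliased columns among: "
            f"{names}"
        )
    rows = []
    all_idx = np.arange(R.shape[0])
    for term, idx in groups:
        idx = np.asarray(idx)
        other = np.setdiff1d(all_idx, idx)
        s1, ld1 = np.linalg.slogdet(R[np.ix_(idx, idx)])
        if other.size:
            s2, ld2 = np.linalg.slogdet(R[np.ix_(other, other)])
        else:
            s2, ld2 = 1.0, 0.0
        if s1 <= 0 or s2 <= 0:
            raise DegenerateDataError(
                f"singular correlation submatrix for term {term!r}"
            )
        gvif = float(np.exp(ld1 + ld2 - logdet_all))
        dfm = len(idx)
        adj = gvif ** (1.0 / (2.0 * dfm))
        rows.append(
            {
                "term": term,
                "gvif": gvif,
                "df": dfm,
                "gvif_adj": adj,
                "flagged": adj > GVIF_THRESHOLD,
            }
        )
    return pd.DataFrame(rows)


def fit_survey_logistic(
    table: RespondentTable,
    spec: ModelSpec,
    *,
    max_iter: int = 100,
    tol: float = 1e-10,
    compute_diagnostics: bool = True,
) -> FitResult:
    """Design-weighted logistic regression with linearized covariance.

    The table must be a completed dataset (no MISSING in the adjustment
    variables is required — MISSING, when present, is treated as an
    ordinary level) with populated design columns.
    """
    df = table.df
    d = table.design
    table.require_columns([spec.outcome, spec.exposure, d.stratum, d.psu,
                           d.weight])
    y = df[spec.outcome].to_numpy(dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise SchemaError(f"outcome {spec.outcome!r} must be 0/1")
    w = df[d.weight].to_numpy(dtype=float)
    if np.any(w <= 0):
        raise SchemaError("analysis weights must be strictly positive")
    X, names, groups = _model_matrix(df, spec)
    n, p = X.shape

    # IRLS for the weighted score equations
    beta = np.zeros(p)
    wbar = w / w.sum()
    ybar = float(np.clip(wbar @ y, 1e-10, 1 - 1e-10))
    beta[0] = np.log(ybar / (1 - ybar))
    n_it = 0
    for n_it in range(1, max_iter + 1):
        eta = np.clip(X @ beta, -30, 30)
        mu = 1.0 / (1.0 + np.exp(-eta))
        W = w * mu * (1.0 - mu)
        score = X.T @ (w * (y - mu))
        info = X.T @ (X * W[:, None])
        try:
            delta = np.linalg.solve(info, score)
        except np.linalg.LinAlgError as exc:
            raise DegenerateDataError(
                f"singular weighted information matrix: {exc}"
            ) from exc
        beta += delta
        if np.abs(beta).max() > 30.0:
            j = int(np.abs(beta).argmax())
            raise SeparationError(names[j])
        if np.abs(delta).max() < tol:
            break
    else:
        raise ConvergenceError(
            f"IRLS did not converge in {max_iter} iterations"
        )

    eta = np.clip(X @ beta, -30, 30)
    mu = 1.0 / (1.0 + np.exp(-eta))
    info = X.T @ (X * (w * mu * (1.0 - mu))[:, None])
    bread = np.linalg.inv(info)
    scores = (w * (y - mu))[:, None] * X
    meat, df_design = _linearized_meat(
        scores,
        df[d.stratum].to_numpy(),
        df[d.psu].to_numpy(),
    )
    vcov = bread @ meat @ bread
    vcov = (vcov + vcov.T) / 2.0

    if compute_diagnostics and p > 2:
        gvif = compute_gvif(X[:, 1:], w, [
            (t, [j - 1 for j in idx]) for t, idx in groups
        ], names[1:])
    else:
        gvif = pd.DataFrame(
            columns=["term", "gvif", "df", "gvif_adj", "flagged"]
        )
    return FitResult(
        column_names=names,
        beta=beta,
        vcov=vcov,
        n=n,
        df_design=df_design,
        gvif_table=gvif,
        n_iterations=n_it,
    )


def weighted_prevalence(
    table: RespondentTable,
    variable: str,
    *,
    level: object | None = None,
) -> pd.DataFrame:
    """Design-based prevalence estimates with linearized 95% CIs.

    For a categorical variable each observed level gets a row; for a
    numeric 0/1 variable the prevalence of 1 is reported.  ``level``
    restricts the output to one level.  The estimator is the weighted
    ratio sum(w * 1[x = level]) / sum(w); its variance comes from the
    stratum/PSU aggregation of the linearized residuals
    w_i (z_i - p_hat) / sum(w).
    """
    df = table.df
    d = table.design
    table.require_columns([variable, d.stratum, d.psu, d.weight])
    w = df[d.weight].to_numpy(dtype=float)
    W = w.sum()
    if W <= 0:
        raise DegenerateDataError("total weight is zero")
    s = df[variable]
    if pd.api.types.is_numeric_dtype(s):
        levels = [1] if level is None else [level]
        vals = s.to_numpy()
    else:
        vals = s.astype(str).to_numpy()
        levels = list(pd.unique(vals)) if level is None else [str(level)]
    rows = []
    for lv in levels:
        z = (vals == lv).astype(float)
        est = float((w * z).sum() / W)
        resid = (w * (z - est) / W)[:, None]
        meat, _ = _linearized_meat(
            resid, df[d.stratum].to_numpy(), df[d.psu].to_numpy()
        )
        se = float(np.sqrt(meat[0, 0]))
        rows.append(
            {
                "level": lv,
                "estimate": est,
                "se": se,
                "ci_low": max(0.0, est - 1.96 * se),
                "ci_high": min(1.0, est + 1.96 * se),
            }
        )
    return pd.DataFrame(rows)
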