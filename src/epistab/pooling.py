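"""Rubin's rules for combining per-imputation survey-model fits.

Estimates are pooled on the log-odds scale (where the normal approximation
underlying the rules is reasonable) and exponentiated last.  With m
imputations, point estimates q_l and squared standard errors u_l:

    q_bar = mean(q_l)
    W     = mean(u_l)                (within-imputation variance)
    B     = var(q_l, ddof=1)         (between-imputation variance)
    T     = W + (1 + 1/m) B          (total variance)

Confidence intervals use a t reference with the Barnard-Rubin
small-sample degrees of freedom, which shrink toward the complete-data
(design) degrees of freedom when the missing-information fraction is
large and never exceed them.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import ConfigurationError

__all__ = ["PooledEffect", "pool_rubin", "barnard_rubin_df"]


@dataclass
class PooledEffect:
    """Rubin-combined odds ratio for one disability x model cell."""

    disability: str
    model: str
    q_bar: float
    W: float
    B: float
    T: float
    df: float
    or_: float
    ci: tuple[float, float]
    m: int
    n_mean: float

    @property
    def significant(self) -> bool:
        """True when the 95% CI excludes an odds ratio of 1."""
        return self.ci[0] > 1.0 or self.ci[1] < 1.0

    def to_dict(self) -> dict:
        return {
            "disability": self.disability,
            "model": self.model,
            "n_mean": self.n_mean,
            "or": self.or_,
            "ci_low": self.ci[0],
            "ci_high": self.ci[1],
            "log_odds": self.q_bar,
            "within_var": self.W,
            "between_var": self.B,
            "total_var": self.T,
            "df": self.df,
            "m": self.m,
        }


def barnard_rubin_df(m: int, B: float, T: float, df_complete: float) -> float:
    """Barnard-Rubin adjusted degrees of freedom, capped at df_complete."""
    if B <= 0.0 or T <= 0.0:
        return float(df_complete)
    lam = (1.0 + 1.0 / m) * B / T
    lam = min(lam, 1.0 - 1e-12)
    df_old = (m - 1) / lam ** 2
    df_obs = (
        (df_complete + 1.0) / (df_complete + 3.0) * df_complete * (1.0 - lam)
    )
    df = 1.0 / (1.0 / df_old + 1.0 / df_obs)
    return float(min(df, df_complete))


def pool_rubin(
    estimates: np.ndarray,
    variances: np.ndarray,
    df_complete: float,
    *,
    disability: str = "",
    model: str = "",
    n_mean: float = float("nan"),
    alpha: float = 0.05,
) -> PooledEffect:
    """Combine m per-imputation log-odds estimates and squared SEs.

    ``df_complete`` is the complete-data (survey design) degrees of
    freedom.  With m = 1 the single fit is returned unchanged (with a
    warning): no between-imputation variance can be estimated.
    """
    estimates = np.asarray(estimates, dtype=float)
    variances = np.asarray(variances, dtype=float)
    if estimates.shape != variances.shape or estimates.ndim != 1:
        raise ConfigurationError(
            "estimates and variances must be equal-length vectors"
        )
    m = len(estimates)
    if m < 1:
        raise ConfigurationError("need at least one imputation")
    if m == 1:
        warnings.warn(
            "pooling a single imputation: between-imputation variance is "
            "undefined and set to 0",
            stacklevel=2,
        )
        q_bar = float(estimates[0])
        W = float(variances[0])
        B = 0.0
        T = W
        df = float(df_complete)
    else:
        q_bar = float(estimates.mean())
        W = float(variances.mean())
        B = float(estimates.var(ddof=1))
        T = W + (1.0 + 1.0 / m) * B
        df = barnard_rubin_df(m, B, T, df_complete)
    half = stats.t.ppf(1.0 - alpha / 2.0, df) * math.sqrt(T) if T > 0 else 0.0

    def _exp(x: float) -> float:
        # wide CIs at near-zero df can push the bound past float range
        return math.exp(min(x, 700.0))

    return PooledEffect(
        disability=disability,
        model=model,
        q_bar=q_bar,
        W=W,
        B=B,
        T=T,
        df=df,
        or_=_exp(q_bar),
        ci=(_exp(q_bar - half), _exp(q_bar + half)),
        m=m,
        n_mean=n_mean,
    )
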