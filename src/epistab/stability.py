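"""Stability selection over repeated-subsample penalized fits, and the
both-endpoints intersection rule that defines confounders.

For each of two binary endpoints — the disability of interest and current
e-cigarette use — the procedure repeats many times: draw a random
subsample, choose the penalty by stratified 10-fold cross-validation,
refit at that penalty, and record which candidate variables carry a
nonzero coefficient on a non-MISSING level.  Variables selected in more
than a threshold fraction of iterations (default: >95% of 300) count as
associated with that endpoint; variables associated with *both* endpoints
form the confounder set, to which the forced demographics (age, gender,
race/ethnicity) are always added.

Penalized fits are unweighted: the survey design enters only the final
regression models, selection being a screening step.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, DegenerateDataError
from .lasso import (
    encode_candidates,
    fit_lasso_path,
    lambda_grid,
    lambda_max,
    select_lambda_min,
    standardize,
    variable_selected_at,
)
from .preprocess import FORCED_DEMOGRAPHICS, RespondentTable

__all__ = ["StabilityConfig", "StabilityReport", "ConfounderSet",
           "stability_select", "intersect_confounders"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class StabilityConfig:
    """Settings of the repeated-subsample selection procedure.

    Defaults follow the reference analysis: 300 iterations on 80%
    subsamples, 10-fold cross-validated penalty, strict >0.95 selection
    threshold, and a 100-point penalty grid down to ``1e-4 * lambda_max``.
    ``cv_seed`` fixes one fold seed for every iteration (useful to make
    iterations exactly reproducible at subsample_fraction = 1); by default
    each iteration gets its own fold stream.
    """

    n_iterations: int = 300
    subsample_fraction: float = 0.8
    cv_folds: int = 10
    selection_threshold: float = 0.95
    seed: int = 0
    n_lambda: int = 100
    lambda_min_ratio: float = 1e-4
    cv_tol: float = 1e-4
    fit_tol: float = 1e-6
    max_class_retries: int = 10
    cv_seed: int | None = None

    def __post_init__(self) -> None:
        if not (0.0 < self.subsample_fraction <= 1.0):
            raise ConfigurationError("subsample_fraction must be in (0, 1]")
        if not (0.0 < self.selection_threshold < 1.0):
            raise ConfigurationError("selection_threshold must be in (0, 1)")
        if self.cv_folds < 2:
            raise ConfigurationError("cv_folds must be at least 2")
        if self.n_iterations < 1 or self.n_lambda < 2:
            raise ConfigurationError("iteration/grid counts too small")


@dataclass
class StabilityReport:
    """Per-variable selection frequencies for one endpoint."""

    endpoint: str
    frequencies: dict[str, float]
    threshold: float
    n_iterations: int

    @property
    def selected(self) -> frozenset[str]:
        """Variables selected strictly more often than the threshold."""
        return frozenset(
            v for v, f in self.frequencies.items() if f > self.threshold
        )

    def to_dict(self) -> dict:
        return {
            "endpoint": self.endpoint,
            "threshold": self.threshold,
            "n_iterations": self.n_iterations,
            "frequencies": dict(sorted(self.frequencies.items())),
            "selected": sorted(self.selected),
        }


@dataclass
class ConfounderSet:
    """Confounders for one disability: the intersection of the variables
    associated with the disability endpoint and with the e-cigarette
    endpoint, always augmented by the forced demographics."""

    disability: str
    confounders: frozenset[str]
    forced: frozenset[str] = field(
        default_factory=lambda: frozenset(FORCED_DEMOGRAPHICS)
    )

    @property
    def adjustment_set(self) -> frozenset[str]:
        return self.confounders | self.forced

    def to_dict(self) -> dict:
        return {
            "disability": self.disability,
            "confounders": sorted(self.confounders),
            "forced": sorted(self.forced),
            "adjustment_set": sorted(self.adjustment_set),
        }


def _endpoint_vector(table: RespondentTable, endpoint: str) -> np.ndarray:
    s = table.df[endpoint]
    vals = s.to_numpy()
    if vals.dtype.kind in "if":
        uniq = set(np.unique(vals))
        if not uniq <= {0, 1, 0.0, 1.0}:
            raise DegenerateDataError(f"endpoint {endpoint!r} is not binary")
        return vals.astype(float)
    uniq = set(np.unique(vals.astype(str)))
    if uniq <= {"yes", "no"}:
        return (vals.astype(str) == "yes").astype(float)
    raise DegenerateDataError(
        f"endpoint {endpoint!r} has non-binary levels {sorted(uniq)}"
    )


def stability_select(
    table: RespondentTable,
    endpoint: str,
    config: StabilityConfig,
    candidates: list[str] | None = None,
) -> StabilityReport:
    """Selection frequencies for one endpoint over repeated subsamples.

    ``candidates`` defaults to the table's candidate-confounder and forced
    demographic variables; the endpoint itself and the counterpart
    endpoint are never candidates (design columns carry the "design" role
    and are excluded by construction).  Reproducible given
    ``config.seed``.
    """
    if candidates is None:
        candidates = table.candidates
    candidates = [c for c in candidates if c != endpoint]
    y_all = _endpoint_vector(table, endpoint)
    if y_all.min() == y_all.max():
        raise DegenerateDataError(
            f"endpoint {endpoint!r} has a single class in this subgroup"
        )
    X_all, coding = encode_candidates(table.df, candidates)
    n = X_all.shape[0]
    m = int(np.ceil(config.subsample_fraction * n))

    counts = {v: 0 for v in coding.variables()}
    root = np.random.SeedSequence(config.seed)
    iter_seeds = root.spawn(config.n_iterations)
    for it in range(config.n_iterations):
        rng = np.random.default_rng(iter_seeds[it])
        if m == n:
            idx = np.arange(n)
        else:
            idx = None
            for _try in range(config.max_class_retries):
                cand_idx = rng.choice(n, size=m, replace=False)
                ysub = y_all[cand_idx]
                if ysub.min() != ysub.max():
                    idx = cand_idx
                    break
            if idx is None:
                raise DegenerateDataError(
                    f"endpoint {endpoint!r}: subsample lost a class in "
                    f"{config.max_class_retries} redraws"
                )
        Xs, keep = standardize(X_all[idx])
        ysub = y_all[idx]
        if Xs.shape[1] == 0:
            continue
        lams = lambda_grid(
            lambda_max(Xs, ysub), config.n_lambda, config.lambda_min_ratio
        )
        cv_rng = (
            np.random.default_rng(config.cv_seed)
            if config.cv_seed is not None
            else rng
        )
        cv = select_lambda_min(
            Xs, ysub,
            n_folds=config.cv_folds,
            rng=cv_rng,
            lambdas=lams,
            cv_tol=config.cv_tol,
        )
        # accurate refit on the subsample, truncated at lambda_min
        betas, _, ncomp = fit_lasso_path(
            Xs, ysub, lams[: cv.lambda_min_index + 1],
            tol=config.fit_tol,
        )
        coefs = betas[min(cv.lambda_min_index, ncomp - 1)]
        for v, hit in variable_selected_at(coefs, coding, keep).items():
            if hit:
                counts[v] += 1
    freqs = {v: c / config.n_iterations for v, c in counts.items()}
    return StabilityReport(
        endpoint=endpoint,
        frequencies=freqs,
        threshold=config.selection_threshold,
        n_iterations=config.n_iterations,
    )


def intersect_confounders(
    report_disability: StabilityReport,
    report_ecig: StabilityReport,
    forced: frozenset[str] = frozenset(FORCED_DEMOGRAPHICS),
    disability: str = "",
) -> ConfounderSet:
    """Variables associated with both endpoints, plus the forced set."""
    confounders = report_disability.selected & report_ecig.selected
    return ConfounderSet(
        disability=disability,
        confounders=frozenset(confounders),
        forced=frozenset(forced),
    )
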