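"""Synthetic survey microdata with known confounding structure.

The generator emulates the features of an annual telephone-survey public
use file that matter to the downstream pipeline: mostly categorical
covariates with an explicit "Refused/not sure/don't know/missing" level,
six binary disability indicators, a binary current-e-cigarette outcome, a
disproportionate stratified design with unequal analysis weights, two
survey-year labels, and missing-at-random covariate missingness.

Ground truth is explicit: one disability indicator is drawn from a logistic
model on the covariates (coefficients ``alpha``), the outcome from a
logistic model on the covariates plus that disability (coefficient
``beta_d`` — the estimand; its exponential is the conditional odds ratio
the pipeline must recover).  Covariates are generated independently of one
another, so the set of true confounders is exactly the set of covariates
with nonzero coefficients in *both* models.  Weights are drawn
independently of the outcome given stratum, so the design-weighted
estimator targets the same conditional odds ratio as the unweighted one.

Missingness is applied only to covariates — never to the outcome, the
disability answers, or the design columns — matching a pipeline that
imputes covariate responses only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .preprocess import (
    DISABILITY_TYPES,
    MISSING,
    DesignColumns,
    RespondentTable,
)

__all__ = [
    "CovariateSpec",
    "MissingnessRule",
    "TruthModel",
    "DesignSpec",
    "generate_population",
    "truth_conditional_or",
    "default_truth",
    "compact_truth",
    "default_design",
]


@dataclass(frozen=True)
class CovariateSpec:
    """Marginal distribution of one covariate.

    ``kind`` is "categorical" (levels with probabilities, binary included)
    or "continuous" (uniform on [lo, hi]).  Continuous coefficients apply
    to ``(x - center) / scale``.
    """

    name: str
    kind: str = "categorical"
    levels: tuple[str, ...] = ()
    probs: tuple[float, ...] = ()
    lo: float = 0.0
    hi: float = 1.0
    center: float = 0.0
    scale: float = 1.0

    def validate(self) -> None:
        if self.kind == "categorical":
            if len(self.levels) < 2 or len(self.levels) != len(self.probs):
                raise ConfigurationError(
                    f"covariate {self.name!r}: levels/probs mismatch"
                )
            if abs(sum(self.probs) - 1.0) > 1e-9 or min(self.probs) < 0:
                raise ConfigurationError(
                    f"covariate {self.name!r}: probabilities must be a "
                    "distribution"
                )
        elif self.kind == "continuous":
            if not (self.hi > self.lo) or self.scale <= 0:
                raise ConfigurationError(
                    f"covariate {self.name!r}: invalid continuous range"
                )
        else:
            raise ConfigurationError(
                f"covariate {self.name!r}: unknown kind {self.kind!r}"
            )


@dataclass(frozen=True)
class MissingnessRule:
    """Missing-at-random rule for one covariate.

    The covariate is set to MISSING with probability ``prob_when`` where
    ``driver == driver_level`` and ``prob_base`` elsewhere; the driver must
    be a fully observed variable.  ``driver=None`` gives MCAR at
    ``prob_base``.
    """

    variable: str
    prob_base: float
    driver: str | None = None
    driver_level: str | None = None
    prob_when: float | None = None

    def validate(self) -> None:
        probs = [self.prob_base]
        if self.driver is not None:
            if self.driver_level is None or self.prob_when is None:
                raise ConfigurationError(
                    f"missingness rule for {self.variable!r}: driver rules "
                    "need driver_level and prob_when"
                )
            probs.append(self.prob_when)
        for p in probs:
            if not (0.0 <= p < 1.0):
                raise ConfigurationError(
                    f"missingness rule for {self.variable!r}: probabilities "
                    "must lie in [0, 1)"
                )


@dataclass(frozen=True)
class TruthModel:
    """Data-generating truth for one modelled disability.

    ``alpha`` and ``beta`` map covariate name -> coefficient: a float for
    continuous covariates, a level -> log-odds mapping for categorical ones
    (absent levels contribute 0).  ``beta_d`` is the conditional log odds
    ratio of the modelled disability on current e-cigarette use — the
    quantity the whole pipeline exists to estimate.  The remaining five
    disability indicators are independent Bernoulli draws at
    ``background_disability_prev``.
    """

    covariate_specs: tuple[CovariateSpec, ...]
    alpha0: float
    alpha: Mapping[str, object]
    beta0: float
    beta_d: float
    beta: Mapping[str, object]
    disability_name: str = "cognitive"
    background_disability_prev: Mapping[str, float] = field(
        default_factory=dict
    )
    missingness: tuple[MissingnessRule, ...] = ()
    forced: tuple[str, ...] = ("age", "gender", "race_ethnicity")

    def __post_init__(self) -> None:
        if self.disability_name not in DISABILITY_TYPES:
            raise ConfigurationError(
                f"disability_name must be one of {DISABILITY_TYPES}"
            )
        names = {s.name for s in self.covariate_specs}
        for s in self.covariate_specs:
            s.validate()
        for rule in self.missingness:
            rule.validate()
            if rule.variable not in names:
                raise ConfigurationError(
                    f"missingness rule targets unknown variable "
                    f"{rule.variable!r}"
                )
        for side in (self.alpha, self.beta):
            for v in side:
                if v not in names:
                    raise ConfigurationError(
                        f"coefficient for unknown covariate {v!r}"
                    )

    @property
    def confounder_names(self) -> frozenset[str]:
        """Covariates with a nonzero coefficient in both models."""

        def active(side: Mapping[str, object]) -> set[str]:
            out = set()
            for v, coef in side.items():
                if isinstance(coef, Mapping):
                    if any(c != 0 for c in coef.values()):
                        out.add(v)
                elif coef != 0:
                    out.add(v)
            return out

        return frozenset(active(self.alpha) & active(self.beta))


@dataclass(frozen=True)
class DesignSpec:
    """Stratified unequal-weight design layout.

    Records are allocated uniformly over ``n_strata`` strata and, within a
    stratum, over ``psu_per_stratum`` primary sampling units.  Analysis
    weights are lognormal(``weight_sigma``) around a stratum base weight;
    base weights are log-spaced over ``stratum_weight_ratio`` so sampling is
    disproportionate across strata.  ``years`` lists survey-year labels
    with per-year sample fractions.
    """

    n_strata: int = 8
    psu_per_stratum: int = 6
    weight_sigma: float = 0.5
    stratum_weight_ratio: float = 4.0
    years: tuple[tuple[str, float], ...] = (("2016", 0.5), ("2017", 0.5))

    def validate(self) -> None:
        if self.n_strata < 1 or self.psu_per_stratum < 1:
            raise ConfigurationError("design counts must be at least 1")
        if self.weight_sigma < 0 or self.stratum_weight_ratio < 1:
            raise ConfigurationError("invalid weight law")
        fracs = [f for _, f in self.years]
        if not self.years or abs(sum(fracs) - 1.0) > 1e-9 or min(fracs) < 0:
            raise ConfigurationError("year fractions must be a distribution")


def default_design() -> DesignSpec:
    return DesignSpec()


def _contribution(
    spec: CovariateSpec, values: np.ndarray, coef: object
) -> np.ndarray:
    """Linear-predictor contribution of one covariate."""
    if spec.kind == "continuous":
        return float(coef) * (values.astype(float) - spec.center) / spec.scale
    if not isinstance(coef, Mapping):
        raise ConfigurationError(
            f"categorical covariate {spec.name!r} needs a level->coefficient "
            "mapping"
        )
    out = np.zeros(values.shape[0])
    for level, c in coef.items():
        out[values == level] += c
    return out


def generate_population(
    truth: TruthModel,
    design: DesignSpec,
    n: int,
    seed: int,
) -> RespondentTable:
    """Draw ``n`` respondents from the truth model under the given design.

    Generation order: covariates, then the modelled disability, then the
    outcome, then design columns, then covariate missingness.  The result
    is bit-reproducible given ``seed``.
    """
    if n < 1:
        raise ConfigurationError("n must be at least 1")
    design.validate()
    rng = np.random.default_rng(seed)
    cols: dict[str, np.ndarray] = {}

    specs = {s.name: s for s in truth.covariate_specs}
    for s in truth.covariate_specs:
        if s.kind == "categorical":
            cols[s.name] = rng.choice(s.levels, size=n, p=s.probs)
        else:
            cols[s.name] = rng.uniform(s.lo, s.hi, size=n)

    eta_d = np.full(n, truth.alpha0)
    for v, coef in truth.alpha.items():
        eta_d += _contribution(specs[v], cols[v], coef)
    d = rng.random(n) < 1.0 / (1.0 + np.exp(-eta_d))
    cols[truth.disability_name] = np.where(d, "yes", "no")
    for t in DISABILITY_TYPES:
        if t == truth.disability_name:
            continue
        prev = float(truth.background_disability_prev.get(t, 0.0))
        if not (0.0 <= prev < 1.0):
            raise ConfigurationError(f"invalid background prevalence for {t}")
        cols[t] = np.where(rng.random(n) < prev, "yes", "no")

    eta_y = np.full(n, truth.beta0) + truth.beta_d * d
    for v, coef in truth.beta.items():
        eta_y += _contribution(specs[v], cols[v], coef)
    y = (rng.random(n) < 1.0 / (1.0 + np.exp(-eta_y))).astype(int)
    cols["ecig_current"] = y
    cols["ecig_status"] = np.where(y == 1, "current", "never")
    cols["cigs_lifetime"] = rng.integers(0, 100, size=n)

    # design columns: uniform allocation over strata and PSUs, lognormal
    # weights around log-spaced stratum base weights, year labels by the
    # specified fractions
    stratum_idx = rng.integers(0, design.n_strata, size=n)
    psu_idx = rng.integers(0, design.psu_per_stratum, size=n)
    if design.n_strata > 1:
        base = design.stratum_weight_ratio ** (
            stratum_idx / (design.n_strata - 1)
        )
    else:
        base = np.ones(n)
    weight = base * rng.lognormal(0.0, design.weight_sigma, size=n)
    year_labels = np.array([yl for yl, _ in design.years])
    year_fracs = np.array([f for _, f in design.years])
    year = rng.choice(year_labels, size=n, p=year_fracs)
    dc = DesignColumns()
    cols[dc.stratum] = np.char.add("S", stratum_idx.astype(str))
    cols[dc.psu] = np.char.add(
        np.char.add(cols[dc.stratum], "_P"), psu_idx.astype(str)
    )
    cols[dc.weight] = weight
    cols[dc.year] = year

    # MAR missingness, applied last and only to covariates
    for rule in truth.missingness:
        spec = specs[rule.variable]
        p_miss = np.full(n, rule.prob_base)
        if rule.driver is not None:
            p_miss = np.where(
                cols[rule.driver] == rule.driver_level,
                rule.prob_when,
                rule.prob_base,
            )
        mask = rng.random(n) < p_miss
        if spec.kind == "continuous":
            vals = cols[rule.variable].astype(float)
            vals[mask] = np.nan
            cols[rule.variable] = vals
        else:
            vals = cols[rule.variable].astype(object)
            vals[mask] = MISSING
            cols[rule.variable] = vals

    df = pd.DataFrame(cols)
    roles: dict[str, str] = {}
    for s in truth.covariate_specs:
        roles[s.name] = "forced" if s.name in truth.forced else "candidate"
    for t in DISABILITY_TYPES:
        roles[t] = "exposure"
    roles["ecig_current"] = "outcome"
    roles["ecig_status"] = "auxiliary"
    roles["cigs_lifetime"] = "auxiliary"
    for c in dc.as_tuple():
        roles[c] = "design"
    return RespondentTable(df, roles, dc)


def truth_conditional_or(truth: TruthModel) -> float:
    """The conditional odds ratio the pipeline must recover: exp(beta_d)."""
    return math.exp(truth.beta_d)


# ---------------------------------------------------------------------------
# preset truth models
# ---------------------------------------------------------------------------

def compact_truth(
    beta_d: float = math.log(1.5),
    *,
    confounder_strength: tuple[float, float] = (0.8, 0.7),
    with_missingness: bool = True,
) -> TruthModel:
    """Small truth model for simulation studies.

    One true confounder (employment status, with a MISSING-prone answer),
    one pure-noise covariate (regular exercise), and the three forced
    demographics.  Demographics affect the outcome only, so the designed
    confounder set is exactly ``{employment}``.  Prevalences target roughly
    10% for the modelled (cognitive) disability and 5% for current
    e-cigarette use, the order of magnitude seen in young-adult
    never-smoker survey data.
    """
    a_emp, b_emp = confounder_strength
    specs = (
        CovariateSpec("age", "continuous", lo=18.0, hi=34.0, center=26.0,
                      scale=5.0),
        CovariateSpec("gender", levels=("female", "male"), probs=(0.55, 0.45)),
        CovariateSpec(
            "race_ethnicity",
            levels=("white", "black", "hispanic"),
            probs=(0.6, 0.18, 0.22),
        ),
        CovariateSpec(
            "employment", levels=("employed", "not_employed"),
            probs=(0.7, 0.3),
        ),
        CovariateSpec("exercise", levels=("yes", "no"), probs=(0.75, 0.25)),
    )
    missingness = ()
    if with_missingness:
        missingness = (
            MissingnessRule(
                "employment", 0.05, driver="gender",
                driver_level="male", prob_when=0.12,
            ),
            MissingnessRule("exercise", 0.06),
        )
    return TruthModel(
        covariate_specs=specs,
        alpha0=-2.6,
        alpha={"employment": {"not_employed": a_emp}},
        beta0=-3.4,
        beta_d=beta_d,
        beta={
            "employment": {"not_employed": b_emp},
            "gender": {"male": 0.3},
            "race_ethnicity": {"black": -0.2, "hispanic": 0.1},
            "age": -0.3,
        },
        disability_name="cognitive",
        background_disability_prev={
            "vision": 0.005,
            "hearing": 0.004,
            "mobility": 0.005,
            "independent_living": 0.005,
            "self_care": 0.003,
        },
        missingness=missingness,
    )


def selection_benchmark_truth(
    n_confounders: int = 3,
    n_noise: int = 7,
    beta_d: float = math.log(1.5),
) -> TruthModel:
    """Truth model for benchmarking confounder recovery.

    Binary candidates only: ``n_confounders`` variables carry strong
    effects on both the disability and the outcome (log-odds 1.0 and 0.9),
    the remaining ``n_noise`` are pure noise.  No forced demographics and
    no missingness, so the stability stage is measured in isolation.
    """
    specs = tuple(
        CovariateSpec(f"conf{j}", levels=("no", "yes"), probs=(0.6, 0.4))
        for j in range(n_confounders)
    ) + tuple(
        CovariateSpec(f"noise{j}", levels=("no", "yes"), probs=(0.6, 0.4))
        for j in range(n_noise)
    )
    alpha = {f"conf{j}": {"yes": 1.0} for j in range(n_confounders)}
    beta = {f"conf{j}": {"yes": 0.9} for j in range(n_confounders)}
    return TruthModel(
        covariate_specs=specs,
        alpha0=-2.2,
        alpha=alpha,
        beta0=-2.8,
        beta_d=beta_d,
        beta=beta,
        disability_name="cognitive",
        forced=(),
    )


def default_truth(beta_d: float = math.log(1.5)) -> TruthModel:
    """Survey-scale truth model with ~15 mostly categorical covariates.

    Three designed confounders (employment, veteran status, income) carry
    nonzero coefficients in both the disability and the outcome model; the
    remaining candidates are noise on one side or both.  Marginals are
    loosely survey-like but make no attempt to match any real codebook.
    """
    specs = (
        CovariateSpec("age", "continuous", lo=18.0, hi=34.0, center=26.0,
                      scale=5.0),
        CovariateSpec("gender", levels=("female", "male"), probs=(0.55, 0.45)),
        CovariateSpec(
            "race_ethnicity",
            levels=("white", "black", "hispanic", "other"),
            probs=(0.55, 0.15, 0.2, 0.1),
        ),
        CovariateSpec(
            "employment",
            levels=("employed", "unemployed", "student", "unable_to_work"),
            probs=(0.6, 0.12, 0.22, 0.06),
        ),
        CovariateSpec("veteran", levels=("no", "yes"), probs=(0.94, 0.06)),
        CovariateSpec(
            "income",
            levels=("<25k", "25-50k", "50-75k", ">=75k"),
            probs=(0.3, 0.3, 0.2, 0.2),
        ),
        CovariateSpec(
            "education",
            levels=("<=hs", "some_college", "college+"),
            probs=(0.35, 0.35, 0.3),
        ),
        CovariateSpec(
            "marital", levels=("single", "married", "other"),
            probs=(0.55, 0.35, 0.1),
        ),
        CovariateSpec("metro", levels=("urban", "rural"), probs=(0.8, 0.2)),
        CovariateSpec("exercise", levels=("yes", "no"), probs=(0.75, 0.25)),
        CovariateSpec("internet", levels=("yes", "no"), probs=(0.9, 0.1)),
        CovariateSpec("own_home", levels=("no", "yes"), probs=(0.6, 0.4)),
        CovariateSpec("insured", levels=("yes", "no"), probs=(0.85, 0.15)),
        CovariateSpec(
            "checkup",
            levels=("<1y", "1-2y", ">2y"),
            probs=(0.5, 0.25, 0.25),
        ),
        CovariateSpec(
            "alcohol", levels=("none", "moderate", "heavy"),
            probs=(0.45, 0.45, 0.1),
        ),
        CovariateSpec(
            "seatbelt", levels=("always", "not_always"), probs=(0.85, 0.15),
        ),
    )
    return TruthModel(
        covariate_specs=specs,
        alpha0=-2.9,
        alpha={
            "employment": {"unemployed": 0.7, "unable_to_work": 1.4},
            "veteran": {"yes": 0.5},
            "income": {"<25k": 0.6, "25-50k": 0.3},
            "education": {"<=hs": 0.3},
            "marital": {"other": 0.2},
        },
        beta0=-3.6,
        beta_d=beta_d,
        beta={
            "employment": {"unemployed": 0.5, "unable_to_work": 0.6},
            "veteran": {"yes": 0.4},
            "income": {"<25k": 0.4, "25-50k": 0.2},
            "alcohol": {"heavy": 0.6, "moderate": 0.3},
            "seatbelt": {"not_always": 0.3},
            "gender": {"male": 0.3},
            "race_ethnicity": {"black": -0.3, "hispanic": 0.1},
            "age": -0.3,
        },
        disability_name="cognitive",
        background_disability_prev={
            "vision": 0.021,
            "hearing": 0.013,
            "mobility": 0.023,
            "independent_living": 0.028,
            "self_care": 0.008,
        },
        missingness=(
            MissingnessRule(
                "income", 0.08, driver="gender", driver_level="male",
                prob_when=0.14,
            ),
            MissingnessRule(
                "employment", 0.03, driver="gender", driver_level="male",
                prob_when=0.06,
            ),
            MissingnessRule("insured", 0.04),
            MissingnessRule("checkup", 0.06),
        ),
    )
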