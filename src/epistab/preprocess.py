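"""Respondent-table container and survey preprocessing.

This module owns the in-memory representation of survey microdata — a pandas
DataFrame plus a role map and the names of the design columns — and the
preprocessing steps applied before modelling:

* inclusion criteria (young adult never-smokers who are never or current
  e-cigarette users),
* derivation of the per-respondent disability profile from the six
  HHS-recommended disability questions,
* collapsing of "refused / not sure / don't know / missing" sentinel codes
  into one explicit MISSING level, with skip-pattern backfill from gate
  questions,
* combined-year weight adjustment for analyses that pool multiple annual
  survey files,
* construction of the per-disability analysis subgroups (respondents with
  the disability of interest plus respondents with no disability at all).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, SchemaError

#: Explicit categorical level holding "Refused/not sure/don't know/missing".
MISSING = "MISSING"

#: The six disability questions, in the order they are usually reported.
DISABILITY_TYPES = (
    "vision",
    "hearing",
    "cognitive",
    "mobility",
    "independent_living",
    "self_care",
)

#: Valid disability subgroup names: "any" plus the six specific types.
DISABILITIES = ("any",) + DISABILITY_TYPES

#: Demographics forced into every adjustment set.
FORCED_DEMOGRAPHICS = frozenset({"age", "gender", "race_ethnicity"})

# Variable roles.  "exposure" marks the six raw disability answers,
# "outcome" the binary current-e-cigarette indicator, "candidate" the
# candidate confounders screened by stability selection, "forced" the
# demographics included in every model, "design" the survey design columns,
# and "auxiliary" bookkeeping columns (inclusion-criteria questions, derived
# profile columns).
ROLES = ("exposure", "outcome", "candidate", "forced", "design", "auxiliary")


@dataclass(frozen=True)
class DesignColumns:
    """Names of the survey design columns."""

    stratum: str = "stratum"
    psu: str = "psu"
    weight: str = "weight"
    year: str = "year"

    def as_tuple(self) -> tuple[str, str, str, str]:
        return (self.stratum, self.psu, self.weight, self.year)


@dataclass
class RespondentTable:
    """Typed survey microdata with variable roles and design columns.

    Parameters
    ----------
    df : DataFrame
        One row per respondent.  Categorical variables are stored as
        strings and may contain the explicit :data:`MISSING` level;
        continuous variables are floats with NaN as their missing marker.
    roles : mapping
        variable name -> one of :data:`ROLES`.
    design : DesignColumns
        Names of the stratum / PSU / weight / year columns.
    exposure_indicator : str or None
        Set by :func:`build_subgroup`: the 0/1 disability-of-interest
        column used as the model exposure.
    """

    df: pd.DataFrame
    roles: dict[str, str]
    design: DesignColumns = field(default_factory=DesignColumns)
    exposure_indicator: str | None = None

    def __post_init__(self) -> None:
        for col, role in self.roles.items():
            if role not in ROLES:
                raise SchemaError(f"unknown role {role!r} for column {col!r}")

    # -- role-based accessors -------------------------------------------
    def columns_with_role(self, role: str) -> list[str]:
        return [c for c, r in self.roles.items() if r == role]

    @property
    def candidates(self) -> list[str]:
        """Candidate confounders, including the forced demographics."""
        return [c for c, r in self.roles.items() if r in ("candidate", "forced")]

    @property
    def forced(self) -> list[str]:
        return self.columns_with_role("forced")

    @property
    def outcome(self) -> str:
        cols = self.columns_with_role("outcome")
        if len(cols) != 1:
            raise SchemaError(f"expected exactly one outcome column, got {cols}")
        return cols[0]

    def require_columns(self, names: Iterable[str]) -> None:
        missing = [n for n in names if n not in self.df.columns]
        if missing:
            raise SchemaError(f"required column(s) absent: {missing}")

    def copy(self) -> "RespondentTable":
        return RespondentTable(
            self.df.copy(), dict(self.roles), self.design, self.exposure_indicator
        )

    def _with_df(self, df: pd.DataFrame) -> "RespondentTable":
        return replace(self, df=df, roles=dict(self.roles))

    # -- serialization ---------------------------------------------------
    def to_csv(self, path: str | Path) -> None:
        """Write the data as CSV plus a JSON sidecar schema (same stem,
        ``.schema.json`` suffix) naming every column's role."""
        path = Path(path)
        self.df.to_csv(path, index=False)
        schema = {
            "roles": self.roles,
            "design": {
                "stratum": self.design.stratum,
                "psu": self.design.psu,
                "weight": self.design.weight,
                "year": self.design.year,
            },
            "exposure_indicator": self.exposure_indicator,
            "continuous": [
                c
                for c in self.df.columns
                if pd.api.types.is_numeric_dtype(self.df[c])
            ],
        }
        path.with_suffix(".schema.json").write_text(json.dumps(schema, indent=2))

    @classmethod
    def from_csv(cls, path: str | Path) -> "RespondentTable":
        """Read a CSV written by :meth:`to_csv` together with its sidecar."""
        path = Path(path)
        schema = json.loads(path.with_suffix(".schema.json").read_text())
        continuous = set(schema.get("continuous", []))
        df = pd.read_csv(path, dtype=str)
        for c in df.columns:
            if c in continuous:
                df[c] = pd.to_numeric(df[c])
        return cls(
            df,
            dict(schema["roles"]),
            DesignColumns(**schema["design"]),
            schema.get("exposure_indicator"),
        )


# ---------------------------------------------------------------------------
# inclusion criteria
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class InclusionCriteria:
    """Analysis population: 18-34-year-old never-smokers (fewer than 100
    lifetime cigarettes) who are never or current e-cigarette users."""

    age_min: float = 18.0
    age_max: float = 34.0
    lifetime_cigarette_threshold: int = 100
    eligible_ecig_statuses: frozenset[str] = frozenset({"never", "current"})

    def __post_init__(self) -> None:
        if self.age_min > self.age_max:
            raise ConfigurationError("age_min must not exceed age_max")
        if self.lifetime_cigarette_threshold <= 0:
            raise ConfigurationError("cigarette threshold must be positive")


def apply_inclusion(
    table: RespondentTable,
    criteria: InclusionCriteria = InclusionCriteria(),
    *,
    age_col: str = "age",
    cigarettes_col: str = "cigs_lifetime",
    ecig_status_col: str = "ecig_status",
) -> RespondentTable:
    """Keep respondents meeting all three inclusion criteria, in order.

    Never-smoker means *strictly fewer* than the lifetime-cigarette
    threshold; former ("ever but not current") e-cigarette users are
    excluded entirely.
    """
    table.require_columns([age_col, cigarettes_col, ecig_status_col])
    df = table.df
    keep = (
        df[age_col].ge(criteria.age_min)
        & df[age_col].le(criteria.age_max)
        & df[cigarettes_col].lt(criteria.lifetime_cigarette_threshold)
        & df[ecig_status_col].isin(criteria.eligible_ecig_statuses)
    )
    return table._with_df(df.loc[keep].reset_index(drop=True))


# ---------------------------------------------------------------------------
# disability profile
# ---------------------------------------------------------------------------

_DISABILITY_LEVELS = {"yes", "no", MISSING}


def derive_disability(
    table: RespondentTable, *, any_col: str = "any_disability"
) -> RespondentTable:
    """Append the any-disability column derived from the six answers.

    ``any`` is "yes" iff at least one type is "yes"; "no" iff all six are
    "no"; otherwise :data:`MISSING` (a respondent with missing answers and
    no "yes" cannot be classified into either group).
    """
    table.require_columns(DISABILITY_TYPES)
    df = table.df
    answers = df[list(DISABILITY_TYPES)]
    bad = set(np.unique(answers.values.astype(str))) - _DISABILITY_LEVELS
    if bad:
        raise SchemaError(f"unknown disability answer level(s): {sorted(bad)}")
    any_yes = answers.eq("yes").any(axis=1)
    all_no = answers.eq("no").all(axis=1)
    out = df.copy()
    out[any_col] = np.where(any_yes, "yes", np.where(all_no, "no", MISSING))
    new = table._with_df(out)
    new.roles[any_col] = "auxiliary"
    return new


# ---------------------------------------------------------------------------
# sentinel recoding and skip-pattern backfill
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BackfillRule:
    """Fill a skip-pattern hole: when ``gate_var == gate_level`` and the
    target is a sentinel/missing, the target's value is determined by the
    survey's routing and can be set to ``fill_level``."""

    gate_var: str
    gate_level: str
    target_var: str
    fill_level: str


def recode_missing(
    table: RespondentTable,
    sentinels: Mapping[str, Sequence[str]],
    *,
    backfill: Sequence[BackfillRule] = (),
    declared_levels: Mapping[str, Sequence[str]] | None = None,
) -> RespondentTable:
    """Collapse declared sentinel codes into the explicit MISSING level.

    Backfill rules run first, so values that are derivable from a gate
    question are recovered rather than marked missing.  If
    ``declared_levels`` is given, a sentinel that collides with a genuine
    level raises :class:`ConfigurationError`.
    """
    if declared_levels:
        for col, codes in sentinels.items():
            clash = set(codes) & set(declared_levels.get(col, ()))
            if clash:
                raise ConfigurationError(
                    f"sentinel(s) {sorted(clash)} collide with genuine levels "
                    f"of column {col!r}"
                )
    df = table.df.copy()
    for rule in backfill:
        if rule.gate_var not in df.columns or rule.target_var not in df.columns:
            raise SchemaError(
                f"backfill rule references absent column(s): {rule}"
            )
        codes = set(sentinels.get(rule.target_var, ())) | {MISSING}
        hole = df[rule.target_var].astype(str).isin(codes) & df[
            rule.gate_var
        ].eq(rule.gate_level)
        df.loc[hole, rule.target_var] = rule.fill_level
    for col, codes in sentinels.items():
        if col not in df.columns:
            raise SchemaError(f"sentinel map references absent column {col!r}")
        df[col] = df[col].astype(str).where(
            ~df[col].astype(str).isin(set(codes)), MISSING
        )
    return table._with_df(df)


# ---------------------------------------------------------------------------
# combined-year weight adjustment
# ---------------------------------------------------------------------------

def adjust_weights_for_combined_years(
    table: RespondentTable, n_years: int | None = None
) -> RespondentTable:
    """Divide each analysis weight by the number of pooled survey years and
    make variance strata year-unique.

    With two full-size annual samples and no year privileged, the pooled
    weight is the annual final weight divided by the number of years; the
    year label is concatenated into the stratum id so that variance strata
    never span years.
    """
    d = table.design
    table.require_columns(d.as_tuple())
    df = table.df.copy()
    if n_years is None:
        n_years = int(df[d.year].nunique())
    if n_years < 1:
        raise ConfigurationError("n_years must be at least 1")
    df[d.weight] = df[d.weight] / n_years
    if n_years > 1:
        df[d.stratum] = (
            df[d.year].astype(str) + "_" + df[d.stratum].astype(str)
        )
    return table._with_df(df)


# ---------------------------------------------------------------------------
# disability subgroups
# ---------------------------------------------------------------------------

def build_subgroup(
    table: RespondentTable,
    disability: str,
    *,
    any_col: str = "any_disability",
    indicator_col: str = "disability_case",
) -> RespondentTable:
    """Respondents with the disability of interest plus respondents with no
    disability at all.

    Respondents reporting only *other* disabilities, and respondents whose
    missing answers block classification, are excluded.  The returned table
    carries a 0/1 ``indicator_col`` (1 = disability of interest) exposed as
    :attr:`RespondentTable.exposure_indicator`.
    """
    if disability not in DISABILITIES:
        raise ConfigurationError(
            f"unknown disability {disability!r}; expected one of {DISABILITIES}"
        )
    table.require_columns([any_col])
    df = table.df
    no_dis = df[any_col].eq("no")
    if disability == "any":
        case = df[any_col].eq("yes")
    else:
        case = df[disability].eq("yes")
    keep = case | no_dis
    out = df.loc[keep].reset_index(drop=True).copy()
    out[indicator_col] = case.loc[keep].reset_index(drop=True).astype(int)
    new = RespondentTable(out, dict(table.roles), table.design, indicator_col)
    new.roles[indicator_col] = "auxiliary"
    return new
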