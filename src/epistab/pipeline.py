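"""End-to-end orchestration: preprocess -> per-subgroup stability selection
(two endpoints) -> confounder intersection -> chained-equation imputation ->
per-imputation design-weighted fits (Model 1 and Model 2) -> Rubin pooling
-> report, plus a simulation-study mode that measures how well the whole
pipeline recovers a known conditional odds ratio.

Two configuration profiles are provided.  The ``reference`` profile
carries the full-scale analysis settings (300 stability iterations,
100-point penalty grid, m = 50 imputations with 30 sweeps).  The ``test``
profile is the desk-scale variant used by the simulation studies: 100
stability iterations on a 16-point grid, m = 10 imputations with 10
sweeps.

Seeding: one master seed expands deterministically into per-disability,
per-stage streams keyed by the disability *name* (not its position), so
adding or removing a disability from the configuration never changes
another disability's results.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import EpistabError
from .mice import ImputationConfig, convergence_diagnostics, impute
from .pooling import PooledEffect, pool_rubin
from .preprocess import (
    DISABILITIES,
    FORCED_DEMOGRAPHICS,
    RespondentTable,
    adjust_weights_for_combined_years,
    apply_inclusion,
    build_subgroup,
    derive_disability,
)
from .stability import (
    ConfounderSet,
    StabilityConfig,
    StabilityReport,
    intersect_confounders,
    stability_select,
)
from .survey import ModelSpec, fit_survey_logistic
from .synthetic import DesignSpec, TruthModel, generate_population, \
    truth_conditional_or

__all__ = [
    "PipelineConfig",
    "DisabilityRow",
    "AnalysisResult",
    "SimulationStudyResult",
    "run_analysis",
    "run_simulation_study",
    "stability_recovery_study",
    "prepare_table",
]

logger = logging.getLogger(__name__)


def _stage_seed(master: int, disability: str, stage: str) -> int:
    """Deterministic per-disability, per-stage seed below 2^31."""
    key = zlib.crc32(f"{disability}/{stage}".encode())
    ss = np.random.SeedSequence((master, key))
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


@dataclass(frozen=True)
class PipelineConfig:
    """Settings for one end-to-end analysis."""

    stability: StabilityConfig = field(default_factory=StabilityConfig)
    imputation: ImputationConfig = field(default_factory=ImputationConfig)
    disabilities: tuple[str, ...] = DISABILITIES
    forced: frozenset[str] = frozenset(FORCED_DEMOGRAPHICS)
    seed: int = 0
    output_dir: str | None = None

    @classmethod
    def reference_profile(cls, seed: int = 0, **kw) -> "PipelineConfig":
        return cls(
            stability=StabilityConfig(n_iterations=300, n_lambda=100,
                                      lambda_min_ratio=1e-4),
            imputation=ImputationConfig(m=50, n_chain_iterations=30),
            seed=seed,
            **kw,
        )

    @classmethod
    def test_profile(cls, seed: int = 0, **kw) -> "PipelineConfig":
        return cls(
            stability=StabilityConfig(n_iterations=100, n_lambda=16,
                                      lambda_min_ratio=2e-3),
            imputation=ImputationConfig(m=10, n_chain_iterations=10),
            seed=seed,
            **kw,
        )


@dataclass
class DisabilityRow:
    """One disability's full result: selection, imputation, both models."""

    disability: str
    n_subgroup: int
    confounder_set: ConfounderSet | None = None
    report_disability: StabilityReport | None = None
    report_outcome: StabilityReport | None = None
    model1: PooledEffect | None = None
    model2: PooledEffect | None = None
    gvif_flagged: bool = False
    mice_flagged_variables: tuple[str, ...] = ()
    error: str | None = None


@dataclass
class AnalysisResult:
    rows: list[DisabilityRow]
    config: PipelineConfig

    def to_dataframe(self) -> pd.DataFrame:
        """Final report table: one row per disability, two models."""
        recs = []
        for r in self.rows:
            rec = {"disability": r.disability, "n_subgroup": r.n_subgroup,
                   "error": r.error}
            if r.confounder_set is not None:
                rec["confounders"] = ",".join(
                    sorted(r.confounder_set.confounders)
                )
                rec["adjustment_set_model2"] = ",".join(
                    sorted(r.confounder_set.adjustment_set)
                )
            for label, eff in (("model1", r.model1), ("model2", r.model2)):
                if eff is None:
                    continue
                rec[f"{label}_n_mean"] = eff.n_mean
                rec[f"{label}_or"] = eff.or_
                rec[f"{label}_ci_low"] = eff.ci[0]
                rec[f"{label}_ci_high"] = eff.ci[1]
                rec[f"{label}_W"] = eff.W
                rec[f"{label}_B"] = eff.B
                rec[f"{label}_T"] = eff.T
                rec[f"{label}_df"] = eff.df
            rec["gvif_flagged"] = r.gvif_flagged
            recs.append(rec)
        return pd.DataFrame(recs)

    def write(self, output_dir: str | Path) -> None:
        """Emit the report as TSV + JSON plus stability frequencies."""
        out = Path(output_dir)
        out.mkdir(parents=True, exist_ok=True)
        df = self.to_dataframe()
        df.to_csv(out / "report.tsv", sep="\t", index=False)
        payload = []
        for r in self.rows:
            item: dict = {"disability": r.disability,
                          "n_subgroup": r.n_subgroup, "error": r.error}
            if r.confounder_set is not None:
                item["confounder_set"] = r.confounder_set.to_dict()
            if r.report_disability is not None:
                item["stability_disability"] = r.report_disability.to_dict()
            if r.report_outcome is not None:
                item["stability_outcome"] = r.report_outcome.to_dict()
            for label, eff in (("model1", r.model1), ("model2", r.model2)):
                if eff is not None:
                    item[label] = eff.to_dict()
            payload.append(item)
        (out / "report.json").write_text(json.dumps(payload, indent=2))


def prepare_table(
    table: RespondentTable,
    *,
    inclusion: bool = True,
    combine_years: bool = True,
) -> RespondentTable:
    """Standard preprocessing: inclusion criteria, disability profile,
    combined-year weight adjustment."""
    if inclusion:
        table = apply_inclusion(table)
    table = derive_disability(table)
    if combine_years:
        table = adjust_weights_for_combined_years(table)
    return table


def _log_event(log_records: list[dict] | None, **kw) -> None:
    logger.info("%s", json.dumps(kw, default=str))
    if log_records is not None:
        log_records.append(kw)


def _analyze_one(
    table: RespondentTable,
    disability: str,
    config: PipelineConfig,
    log_records: list[dict] | None,
) -> DisabilityRow:
    t0 = time.perf_counter()
    subgroup = build_subgroup(table, disability)
    row = DisabilityRow(disability=disability, n_subgroup=len(subgroup.df))
    exposure = subgroup.exposure_indicator
    outcome = subgroup.outcome

    # stability selection on both endpoints
    reports = {}
    for stage, endpoint in (("stab_dis", exposure), ("stab_out", outcome)):
        cfg = dataclasses.replace(
            config.stability, seed=_stage_seed(config.seed, disability, stage)
        )
        reports[stage] = stability_select(subgroup, endpoint, cfg)
        _log_event(
            log_records, stage=stage, disability=disability,
            endpoint=endpoint, seed=cfg.seed,
            selected=sorted(reports[stage].selected),
        )
    row.report_disability = reports["stab_dis"]
    row.report_outcome = reports["stab_out"]
    row.confounder_set = intersect_confounders(
        reports["stab_dis"], reports["stab_out"],
        forced=config.forced, disability=disability,
    )

    # chained-equation imputation on the model variable list
    imp_cfg = dataclasses.replace(
        config.imputation, seed=_stage_seed(config.seed, disability, "mice")
    )
    covariates = sorted(row.confounder_set.adjustment_set)
    imp = impute(subgroup, covariates, outcome, exposure, imp_cfg)
    diag = convergence_diagnostics(imp)
    row.mice_flagged_variables = tuple(
        v for v, d in diag.items() if d["flagged"]
    )
    if row.mice_flagged_variables:
        _log_event(log_records, stage="mice_diagnostics",
                   disability=disability,
                   flagged=list(row.mice_flagged_variables))

    # per-imputation design-weighted fits, both models
    spec1 = ModelSpec(outcome, exposure, tuple(sorted(config.forced)))
    spec2 = ModelSpec(
        outcome, exposure, tuple(sorted(row.confounder_set.adjustment_set))
    )
    for label, spec in (("model1", spec1), ("model2", spec2)):
        qs, us, ns, dfs = [], [], [], []
        flagged = False
        for ds in imp.datasets:
            completed = RespondentTable(
                ds, dict(subgroup.roles), subgroup.design, exposure
            )
            fit = fit_survey_logistic(completed, spec)
            q, se = fit.coef(exposure)
            qs.append(q)
            us.append(se ** 2)
            ns.append(fit.n)
            dfs.append(fit.df_design)
            flagged = flagged or bool(fit.gvif_table["flagged"].any())
        pooled = pool_rubin(
            np.array(qs), np.array(us), df_complete=float(min(dfs)),
            disability=disability, model=label, n_mean=float(np.mean(ns)),
        )
        setattr(row, label, pooled)
        row.gvif_flagged = row.gvif_flagged or flagged
        _log_event(
            log_records, stage=label, disability=disability,
            or_=pooled.or_, ci=pooled.ci, gvif_flagged=flagged,
            seconds=round(time.perf_counter() - t0, 2),
        )
    return row


def run_analysis(
    table: RespondentTable, config: PipelineConfig
) -> AnalysisResult:
    """Run the full seven-subgroup (or configured subset) analysis.

    A failure in one disability's pipeline aborts only that row, with the
    reason recorded; remaining disabilities proceed.  Identical config and
    seed reproduce the result bit-identically.
    """
    log_records: list[dict] = []
    rows = []
    for disability in config.disabilities:
        try:
            rows.append(_analyze_one(table, disability, config, log_records))
        except EpistabError as exc:
            logger.warning("disability %s aborted: %s", disability, exc)
            rows.append(DisabilityRow(disability=disability, n_subgroup=0,
                                      error=str(exc)))
    result = AnalysisResult(rows=rows, config=config)
    if config.output_dir:
        result.write(config.output_dir)
        (Path(config.output_dir) / "log.jsonl").write_text(
            "\n".join(json.dumps(r, default=str) for r in log_records)
        )
    return result


def stability_recovery_study(
    truth: TruthModel,
    design: DesignSpec,
    n: int,
    replicates: int,
    stability_config: StabilityConfig,
    seed: int = 0,
) -> pd.DataFrame:
    """Run only the confounder-selection stage on replicated data.

    Per replicate: generate, build the disability subgroup, run stability
    selection for both endpoints, intersect (without forced demographics),
    and score recovery of the truth's confounders.  Returns one row per
    replicate with sensitivity and the noise false-selection rate.
    """
    true_conf = set(truth.confounder_names)
    noise = {
        s.name for s in truth.covariate_specs if s.name not in true_conf
    }
    rows = []
    for rep in range(replicates):
        gen_seed = _stage_seed(seed, f"recovery{rep}", "generate")
        table = generate_population(truth, design, n, gen_seed)
        # no inclusion filtering: benchmark truths need not carry the
        # inclusion-criteria columns
        table = prepare_table(table, inclusion=False)
        subgroup = build_subgroup(table, truth.disability_name)
        reports = {}
        for stage, endpoint in (
            ("dis", subgroup.exposure_indicator),
            ("out", subgroup.outcome),
        ):
            cfg = dataclasses.replace(
                stability_config,
                seed=_stage_seed(seed, f"recovery{rep}", stage),
            )
            reports[stage] = stability_select(subgroup, endpoint, cfg)
        cs = intersect_confounders(
            reports["dis"], reports["out"], forced=frozenset()
        )
        picked = set(cs.confounders)
        rows.append(
            {
                "replicate": rep,
                "sensitivity": (
                    len(picked & true_conf) / len(true_conf)
                    if true_conf else np.nan
                ),
                "false_rate": (
                    len(picked & noise) / len(noise) if noise else 0.0
                ),
                "selected": ",".join(sorted(picked)),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# simulation-study mode
# ---------------------------------------------------------------------------

@dataclass
class SimulationStudyResult:
    """Pipeline operating characteristics over replicated synthetic data."""

    replicates: int
    truth_or: float
    coverage: float
    rejection_rate: float
    selection_sensitivity: float
    false_selection_rate: float
    mean_or_model1: float
    mean_or_model2: float
    details: pd.DataFrame

    def to_dict(self) -> dict:
        return {
            "replicates": self.replicates,
            "truth_or": self.truth_or,
            "coverage": self.coverage,
            "rejection_rate": self.rejection_rate,
            "selection_sensitivity": self.selection_sensitivity,
            "false_selection_rate": self.false_selection_rate,
            "mean_or_model1": self.mean_or_model1,
            "mean_or_model2": self.mean_or_model2,
        }


def run_simulation_study(
    config: PipelineConfig,
    truth: TruthModel,
    design: DesignSpec,
    n: int,
    replicates: int,
) -> SimulationStudyResult:
    """Generate -> analyze repeatedly; aggregate coverage and selection.

    Coverage and rejection refer to the Model 2 pooled CI for the modelled
    disability; selection sensitivity is the fraction of true confounders
    recovered by the intersection rule, and the false-selection rate the
    fraction of noise covariates (candidates that are not true confounders
    and not forced) wrongly admitted.
    """
    if replicates < 1:
        raise ValueError("replicates must be at least 1")
    true_or = truth_conditional_or(truth)
    candidates = {
        s.name for s in truth.covariate_specs if s.name not in truth.forced
    }
    true_conf = set(truth.confounder_names) - set(truth.forced)
    noise = candidates - true_conf
    recs = []
    for rep in range(replicates):
        rep_seed = _stage_seed(config.seed, f"replicate{rep}", "generate")
        table = generate_population(truth, design, n, rep_seed)
        table = prepare_table(table)
        rep_cfg = dataclasses.replace(
            config,
            seed=_stage_seed(config.seed, f"replicate{rep}", "analysis"),
            disabilities=(truth.disability_name,),
            output_dir=None,
        )
        row = run_analysis(table, rep_cfg).rows[0]
        if row.error is not None or row.model2 is None:
            recs.append({"replicate": rep, "error": row.error})
            continue
        eff2 = row.model2
        conf = set(row.confounder_set.confounders) - set(truth.forced)
        recs.append(
            {
                "replicate": rep,
                "error": None,
                "or_model1": row.model1.or_,
                "or_model2": eff2.or_,
                "ci_low": eff2.ci[0],
                "ci_high": eff2.ci[1],
                "covers_truth": eff2.ci[0] <= true_or <= eff2.ci[1],
                "rejects_null": eff2.significant,
                "sensitivity": (
                    len(conf & true_conf) / len(true_conf)
                    if true_conf else np.nan
                ),
                "false_rate": (
                    len(conf & noise) / len(noise) if noise else 0.0
                ),
            }
        )
    details = pd.DataFrame(recs)
    ok = details[details["error"].isna()]
    return SimulationStudyResult(
        replicates=replicates,
        truth_or=true_or,
        coverage=float(ok["covers_truth"].mean()) if len(ok) else np.nan,
        rejection_rate=float(ok["rejects_null"].mean()) if len(ok) else np.nan,
        selection_sensitivity=(
            float(ok["sensitivity"].mean()) if len(ok) else np.nan
        ),
        false_selection_rate=(
            float(ok["false_rate"].mean()) if len(ok) else np.nan
        ),
        mean_or_model1=float(ok["or_model1"].mean()) if len(ok) else np.nan,
        mean_or_model2=float(ok["or_model2"].mean()) if len(ok) else np.nan,
        details=details,
    )
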