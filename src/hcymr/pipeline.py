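"""End-to-end analysis driver: per-study MR, diagnostics, and meta-analysis.

``run_pipeline`` drives the full workflow from summary-statistics files;
``run_packaged_analysis`` runs the same workflow on the packaged
homocysteine/PCOS instrument table.  Both produce a :class:`PipelineReport`
whose tidy tables can be written out as TSV, and record every seed and
option in a run log so identical configurations give byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from . import fixture
from .data_model import (InstrumentSet, SelectionConfig, harmonize,
                         read_summary_stats, select_instruments)
from .estimators import (MREstimate, cochran_q, egger, ivw, wald_ratios,
                         weighted_median, first_order_weights, Z_95)
from .meta_analysis import MetaResult, forest_table, meta_fixed, meta_random
from .robustness import leave_one_out, presso, steiger

__all__ = [
    "OutcomeSpec",
    "PipelineConfig",
    "PipelineReport",
    "PipelineError",
    "AnalysisOptions",
    "analyze_study_sets",
    "run_pipeline",
    "run_packaged_analysis",
]


class PipelineError(RuntimeError):
    """An analysis stage failed; the stage name prefixes the message."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"[{stage}] {cause}")
        self.stage = stage


@dataclass(frozen=True)
class OutcomeSpec:
    """One outcome study: where its table lives and its cohort sizes."""

    label: str
    path: str | Path
    n_cases: int | None = None
    n_controls: int | None = None
    column_map: Mapping[str, str] | None = None


@dataclass(frozen=True)
class AnalysisOptions:
    """Estimator and diagnostic settings shared by all entry points."""

    ivw_model: str = "auto"
    egger_p_reference: str = "normal"
    n_boot: int = 10_000
    boot_seed: int = 12345
    presso_n_sim: int = 5_000
    presso_seed: int = 12345
    meta_model: str = "fixed"


@dataclass(frozen=True)
class PipelineConfig:
    exposure_path: str | Path
    outcomes: Sequence[OutcomeSpec]
    n_exposure: int | None = None
    exposure_column_map: Mapping[str, str] | None = None
    selection: SelectionConfig | None = None
    ld_matrix: object = None
    pleiotropy_flags: Mapping[str, str] | None = None
    options: AnalysisOptions = field(default_factory=AnalysisOptions)
    out_dir: str | Path | None = None

    def __post_init__(self) -> None:
        if len(self.outcomes) < 1:
            raise ValueError("at least one outcome study is required")


@dataclass
class PipelineReport:
    """Tidy result tables plus the run log."""

    tables: dict[str, pd.DataFrame]
    log: list[str]
    study_sets: dict[str, InstrumentSet]
    meta: MetaResult | None

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, df in self.tables.items():
            df.to_csv(out / f"{name}.tsv", sep="\t", index=False,
                      float_format="%.10g")
        (out / "run_log.txt").write_text("\n".join(self.log) + "\n")


def _estimate_row(study: str, est: MREstimate) -> dict:
    return {
        "study": study, "method": est.method,
        "n_instruments": est.n_instruments,
        "estimate_log_odds": est.estimate, "se": est.se,
        "ci_low_log_odds": est.ci_low, "ci_high_log_odds": est.ci_high,
        "p_value": est.p_value,
        "odds_ratio": est.odds_ratio,
        "or_ci_low": est.or_ci_low, "or_ci_high": est.or_ci_high,
    }


def analyze_study_sets(study_sets: Sequence[InstrumentSet],
                       options: AnalysisOptions = AnalysisOptions(),
                       audits: Mapping[str, Sequence[str]] | None = None,
                       extra_log: Sequence[str] = (),
                       ) -> PipelineReport:
    """Run estimators, diagnostics and (if >= 2 studies) meta-analysis."""
    log: list[str] = [
        f"ivw_model={options.ivw_model}",
        f"egger_p_reference={options.egger_p_reference}",
        f"weighted_median n_boot={options.n_boot} seed={options.boot_seed}",
        f"presso n_sim={options.presso_n_sim} seed={options.presso_seed}",
        f"meta_model={options.meta_model}",
        *extra_log,
    ]
    est_rows, inst_rows, het_rows = [], [], []
    presso_rows, steiger_rows, loo_rows, audit_rows = [], [], [], []
    ivw_by_study: list[MREstimate] = []
    labels: list[str] = []

    for iset in study_sets:
        study = iset.label
        labels.append(study)
        for line in (audits or {}).get(study, []):
            audit_rows.append({"study": study, "entry": line})

        try:
            ratios = wald_ratios(iset)
            weights = first_order_weights(iset)
            for inst, ratio, w in zip(iset, ratios, weights):
                se = abs(inst.se_outcome / inst.beta_exposure)
                inst_rows.append({
                    "study": study, "variant_id": inst.variant_id,
                    "beta_exposure": inst.beta_exposure,
                    "se_exposure": inst.se_exposure,
                    "beta_outcome": inst.beta_outcome,
                    "se_outcome": inst.se_outcome,
                    "f_statistic": inst.f_statistic,
                    "wald_ratio": ratio, "wald_se": se,
                    "wald_ci_low": ratio - Z_95 * se,
                    "wald_ci_high": ratio + Z_95 * se,
                    "ivw_weight": w,
                })

            est_ivw = ivw(iset, model=options.ivw_model)
            ivw_by_study.append(est_ivw)
            est_rows.append(_estimate_row(study, est_ivw))
            if len(iset) >= 3:
                egg = egger(iset, p_reference=options.egger_p_reference)
                est_rows.append(_estimate_row(study, egg.slope))
                est_rows.append(_estimate_row(study, egg.intercept))
                wm = weighted_median(iset, n_boot=options.n_boot,
                                     seed=options.boot_seed)
                est_rows.append(_estimate_row(study, wm))
            if len(iset) >= 2:
                het = cochran_q(iset)
                het_rows.append({
                    "study": study, "q_statistic": het.q_statistic,
                    "df": het.df, "p_value": het.p_value,
                    "i_squared": het.i_squared,
                })
        except Exception as exc:  # noqa: BLE001 - re-raised with stage name
            raise PipelineError(f"estimators:{study}", exc) from exc

        try:
            if len(iset) >= 4:
                pres = presso(iset, n_sim=options.presso_n_sim,
                              seed=options.presso_seed)
                presso_rows.append({
                    "study": study,
                    "global_rss_observed": pres.global_rss_observed,
                    "global_p": pres.global_p,
                    "n_outliers": len(pres.outliers),
                    "outliers": ",".join(pres.outliers) or "none",
                    "distortion_p": pres.distortion_p,
                })
            if (iset.n_exposure is not None
                    and iset.n_outcome_cases is not None
                    and iset.n_outcome_controls is not None):
                st = steiger(iset)
                steiger_rows.append({
                    "study": study, "r2_exposure": st.r2_exposure,
                    "r2_outcome": st.r2_outcome,
                    "direction_correct": st.direction_correct,
                    "p_value": st.p_value,
                })
            if len(iset) >= 3:
                loo = leave_one_out(iset, model=options.ivw_model)
                for vid, est in zip(loo.variant_ids, loo.estimates):
                    loo_rows.append({
                        "study": study, "excluded_variant": vid,
                        "estimate_log_odds": est.estimate,
                        "ci_low_log_odds": est.ci_low,
                        "ci_high_log_odds": est.ci_high,
                    })
        except Exception as exc:
            raise PipelineError(f"robustness:{study}", exc) from exc

    tables: dict[str, pd.DataFrame] = {
        "estimates": pd.DataFrame(est_rows),
        "instruments": pd.DataFrame(inst_rows),
        "heterogeneity": pd.DataFrame(het_rows),
        "presso": pd.DataFrame(presso_rows),
        "steiger": pd.DataFrame(steiger_rows),
        "leave_one_out": pd.DataFrame(loo_rows),
        "harmonization_audit": pd.DataFrame(audit_rows,
                                            columns=["study", "entry"]),
    }

    meta: MetaResult | None = None
    if len(ivw_by_study) >= 2:
        try:
            pool = meta_fixed if options.meta_model == "fixed" else meta_random
            meta = pool(ivw_by_study)
            tables["meta"] = forest_table(ivw_by_study, labels, meta)
            log.append(f"meta: pooled {len(labels)} studies "
                       f"(model={meta.model}, Q={meta.q_between:.3f})")
        except Exception as exc:
            raise PipelineError("meta_analysis", exc) from exc
    else:
        log.append("meta: skipped, fewer than 2 outcome studies")

    return PipelineReport(tables=tables, log=log,
                          study_sets={s.label: s for s in study_sets},
                          meta=meta)


def run_pipeline(config: PipelineConfig) -> PipelineReport:
    """Full pipeline from delimited summary-statistics files."""
    try:
        exposure = read_summary_stats(config.exposure_path,
                                      config.exposure_column_map)
    except Exception as exc:
        raise PipelineError("read_exposure", exc) from exc

    selection_log: list[str] = []
    if (config.selection is not None or config.ld_matrix is not None
            or config.pleiotropy_flags is not None):
        try:
            exposure, sel_audit = select_instruments(
                exposure, config.selection, config.ld_matrix,
                config.pleiotropy_flags)
            selection_log = [f"selection: {line}" for line in sel_audit]
        except Exception as exc:
            raise PipelineError("select_instruments", exc) from exc

    study_sets: list[InstrumentSet] = []
    audits: dict[str, list[str]] = {}
    for spec in config.outcomes:
        try:
            outcome = read_summary_stats(spec.path, spec.column_map)
            iset, audit = harmonize(
                exposure, outcome, label=spec.label,
                n_exposure=config.n_exposure,
                n_outcome_cases=spec.n_cases,
                n_outcome_controls=spec.n_controls)
            study_sets.append(iset)
            audits[spec.label] = audit
        except Exception as exc:
            raise PipelineError(f"harmonize:{spec.label}", exc) from exc

    report = analyze_study_sets(study_sets, config.options, audits,
                                extra_log=selection_log)
    if config.out_dir is not None:
        report.write(config.out_dir)
    return report


def run_packaged_analysis(options: AnalysisOptions = AnalysisOptions(),
                          out_dir: str | Path | None = None) -> PipelineReport:
    """The packaged homocysteine -> PCOS analysis across all three cohorts."""
    study_sets = [fixture.study_instrument_set(s) for s in fixture.STUDIES]
    audits = {
        fixture.STUDY_LABELS["finngen"]: [
            f"{vid}\tMISSING_IN_OUTCOME\tno association reported; "
            "no proxy at r2 > 0.8" for vid in fixture.FINNGEN_MISSING],
    }
    report = analyze_study_sets(
        study_sets, options, audits,
        extra_log=["warning: Tyrmi et al. includes FinnGen R6 samples; the "
                   "pooled estimate ignores this partial outcome overlap"])
    if out_dir is not None:
        report.write(out_dir)
    return report
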