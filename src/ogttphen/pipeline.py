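"""End-to-end pipeline: read → indices → classification → subtype →
adjusted models → risk stratification, with stage CSV outputs and a
deterministic human-readable summary.

Stage outputs are separate CSVs so each stage is independently diffable;
log lines (stage- and patient-tagged) go to a logger, data to files. On
any stage error, partially written outputs are removed.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .classify import (DEFAULT_THRESHOLDS, GlycemicThresholds, classify_cohort,
                       subtype_table, summarize_prevalence, SUBTYPES)
from .cohort import CohortTable, UnitConfig, read_cohort
from .errors import CohortError
from .indices import compute_indices
from .models import DEFAULT_COVARIATES, fit_all_outcomes
from .risk import stratify

log = logging.getLogger("ogttphen")

ALL_STAGES = ("indices", "classification", "models", "stratification")


@dataclass(frozen=True)
class RunConfig:
    input_path: str | Path
    output_dir: str | Path
    units: UnitConfig = field(default_factory=UnitConfig)
    thresholds: GlycemicThresholds = DEFAULT_THRESHOLDS
    predictors: tuple[str, ...] = ("age", "bmi")
    covariates: tuple[str, ...] = DEFAULT_COVARIATES
    stages: tuple[str, ...] = ALL_STAGES

    def __post_init__(self):
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise CohortError(f"unknown stage(s): {sorted(unknown)}")


@dataclass
class ReportBundle:
    cohort: CohortTable
    classification: pd.DataFrame
    prevalence: object
    subtypes: dict
    indices: pd.DataFrame | None = None
    model_fits: pd.DataFrame | None = None
    stratification: pd.DataFrame | None = None
    excluded: tuple[tuple[str, str], ...] = ()   # (patient id, reason)


def _usable_for_ogtt(cohort: CohortTable) -> tuple[CohortTable, list[tuple[str, str]]]:
    """Split off records that cannot enter OGTT-based stages, with reasons."""
    excluded = []
    kept = []
    for record in cohort:
        if record.ogtt_partial:
            excluded.append((record.id, "incomplete OGTT (some time points missing)"))
            log.warning("classification: record %s excluded: incomplete OGTT",
                        record.id)
            continue
        kept.append(record)
    return CohortTable(tuple(kept), cohort.provenance), excluded


def run_pipeline(config: RunConfig) -> ReportBundle:
    """Execute the configured stages, writing one CSV per stage plus a
    human-readable ``summary.txt``; removes partial outputs on failure."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def write(frame: pd.DataFrame, name: str) -> None:
        path = out / name
        frame.to_csv(path, index=False)
        written.append(path)

    try:
        cohort = read_cohort(config.input_path, config.units)
        cohort, excluded = _usable_for_ogtt(cohort)
        bundle = ReportBundle(
            cohort=cohort,
            classification=classify_cohort(cohort, config.thresholds),
            prevalence=summarize_prevalence(cohort, config.thresholds),
            subtypes=subtype_table(cohort, config.thresholds),
            excluded=tuple(excluded),
        )
        write(bundle.classification, "classification.csv")
        prev = bundle.prevalence
        write(pd.DataFrame([{
            "n_total": prev.n_total, "n_known_dm": prev.n_known_dm,
            "n_new_dm": prev.n_new_dm, "n_prediabetes": prev.n_prediabetes,
            "n_ngt": prev.n_ngt,
            "pct_any_disturbance": prev.pct_any_disturbance,
            "pct_known_dm": prev.pct_known_dm, "pct_new_dm": prev.pct_new_dm,
            "pct_prediabetes": prev.pct_prediabetes,
            "n_multi_criterion": prev.n_multi_criterion,
        }]), "prevalence.csv")
        write(pd.DataFrame([{"subtype": s, "n": bundle.subtypes[s]}
                            for s in SUBTYPES]), "subtype.csv")

        if "indices" in config.stages:
            bundle.indices = compute_indices(cohort)
            write(bundle.indices, "indices.csv")
        if "models" in config.stages:
            bundle.model_fits = fit_all_outcomes(cohort, config.covariates,
                                                 config.thresholds)
            write(bundle.model_fits, "adjusted_models.csv")
        if "stratification" in config.stages:
            rows = []
            for predictor in config.predictors:
                roc, rr = stratify(cohort, predictor, config.thresholds)
                rows.append({
                    "predictor": predictor, "cutoff": roc.optimal_cutoff,
                    "sens": roc.optimal_sens, "spec": roc.optimal_spec,
                    "auc": roc.auc,
                    "a": rr.table.a, "b": rr.table.b,
                    "c": rr.table.c, "d": rr.table.d,
                    "rr": rr.rr, "ci_low": rr.ci_low, "ci_high": rr.ci_high,
                })
            bundle.stratification = pd.DataFrame(rows)
            write(bundle.stratification, "stratification.csv")

        summary_path = out / "summary.txt"
        summary_path.write_text(render_summary(bundle))
        written.append(summary_path)
        return bundle
    except Exception:
        for path in written:
            path.unlink(missing_ok=True)
        raise


def render_summary(bundle: ReportBundle) -> str:
    """Deterministic plain-text report (integer-percent display rounding)."""
    prev = bundle.prevalence
    pct = prev.display_percentages()
    lines = [
        "Glycemic phenotyping summary",
        "============================",
        f"patients: {prev.n_total} classified"
        + (f", {len(bundle.excluded)} excluded" if bundle.excluded else ""),
        "",
        f"any disturbance: {prev.n_known_dm + prev.n_new_dm + prev.n_prediabetes}"
        f" ({pct['any_disturbance']}%)",
        f"known DM:    {prev.n_known_dm} ({pct['known_dm']}%)",
        f"new DM:      {prev.n_new_dm} ({pct['new_dm']}%)",
        f"prediabetes: {prev.n_prediabetes} ({pct['prediabetes']}%)",
        f"NGT:         {prev.n_ngt} ({100 - pct['any_disturbance']}%)",
        "",
        "prediabetes criteria: "
        + ", ".join(f"{k}={v}" for k, v in sorted(prev.criterion_counts.items()))
        + f"; multi-criterion patients: {prev.n_multi_criterion}",
        "",
        "glucose-tolerance subtypes (non-DM patients):",
    ]
    for s in SUBTYPES:
        lines.append(f"  {s:8s} {bundle.subtypes[s]}")
    if bundle.indices is not None:
        med = bundle.indices[["homa_ir", "matsuda_isi", "igi", "disposition"]].median()
        lines += ["", "index medians (patients with OGTT):"]
        for name, value in med.items():
            lines.append(f"  {name:12s} {value:.2f}")
    if bundle.stratification is not None:
        lines += ["", "risk stratification (prediabetes vs NGT):"]
        for row in bundle.stratification.itertuples(index=False):
            lines.append(
                f"  {row.predictor}: cutoff {row.cutoff:g} "
                f"(sens {row.sens:.2f}, spec {row.spec:.2f}, AUC {row.auc:.2f}); "
                f"RR {row.rr:.2f} [{row.ci_low:.2f}, {row.ci_high:.2f}]"
                if row.rr is not None and row.rr == row.rr else
                f"  {row.predictor}: cutoff {row.cutoff:g}; RR undefined")
    if bundle.excluded:
        lines += ["", "excluded records:"]
        for pid, reason in bundle.excluded:
            lines.append(f"  {pid}: {reason}")
    return "\n".join(lines) + "\n"
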