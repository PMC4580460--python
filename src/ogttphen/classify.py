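"""ADA-based glycemic classification, prevalence summary and subtype grouping.

Categories, in decision order: previously known diabetes; newly diagnosed
diabetes (fasting glucose ≥ 7.0 mmol/l, 2h OGTT glucose ≥ 11.1 mmol/l or
HbA1c ≥ 6.5 %); prediabetes by any of the three band criteria — impaired
fasting glucose (IFG, 5.5–6.9 mmol/l), impaired glucose tolerance
(IGT, 2h 7.8–11.0 mmol/l) or the HbA1c band (5.7–6.4 %); otherwise normal
glucose tolerance (NGT).

Band membership is implemented as ``lower ≤ x < diabetes cutoff``, which
coincides with the printed closed bands at the 0.1-unit measurement
precision but keeps classification total and severity-monotone on the
whole real line.

The glucose-tolerance subtype (NGT / iIFG / iIGT / IFG+IGT) is defined by
the IFG/IGT flags alone: a patient prediabetic solely via the HbA1c band
falls in the NGT subtype bin, while still counting as prediabetes in the
prevalence summary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

from .cohort import CohortTable, PatientRecord
from .errors import DomainError, MissingDataError

CRIT_IFG = "IFG"
CRIT_IGT = "IGT"
CRIT_HBA1C = "HBA1C_BAND"
CRITERIA = (CRIT_IFG, CRIT_IGT, CRIT_HBA1C)

CATEGORIES = ("known_dm", "new_dm", "prediabetes", "ngt")
SUBTYPES = ("NGT", "iIFG", "iIGT", "IFG_IGT")


@dataclass(frozen=True)
class GlycemicThresholds:
    """All band edges and diabetes cutoffs (mmol/l for glucose, % for HbA1c)."""

    ifg_lower: float = 5.5
    ifg_upper: float = 6.9
    igt_lower: float = 7.8
    igt_upper: float = 11.0
    hba1c_lower: float = 5.7
    hba1c_upper: float = 6.4
    dm_fpg: float = 7.0
    dm_2h: float = 11.1
    dm_hba1c: float = 6.5

    def __post_init__(self):
        for lo, hi, cut in ((self.ifg_lower, self.ifg_upper, self.dm_fpg),
                            (self.igt_lower, self.igt_upper, self.dm_2h),
                            (self.hba1c_lower, self.hba1c_upper, self.dm_hba1c)):
            if not lo <= hi < cut:
                raise DomainError(f"inconsistent band ({lo}, {hi}) vs cutoff {cut}")


DEFAULT_THRESHOLDS = GlycemicThresholds()


@dataclass(frozen=True)
class GlycemicStatus:
    category: str
    criteria: frozenset[str] = frozenset()
    subtype: str = "not_applicable"

    def __post_init__(self):
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        if self.category == "prediabetes" and not self.criteria:
            raise ValueError("prediabetes requires at least one criterion")
        if self.category in ("known_dm", "new_dm") and self.subtype != "DM":
            raise ValueError("manifest DM must carry subtype DM")
        if self.category == "ngt" and (self.criteria or self.subtype != "NGT"):
            raise ValueError("NGT carries no criteria and subtype NGT")


def classify_patient(record: PatientRecord,
                     thresholds: GlycemicThresholds = DEFAULT_THRESHOLDS) -> GlycemicStatus:
    """Classify one patient; see module docstring for the decision order.

    Raises :class:`MissingDataError` when the OGTT is absent without the
    contraindication exemption (known DM or fasting glucose ≥ 7 mmol/l).
    """
    t = thresholds
    if record.known_dm != "none":
        return GlycemicStatus("known_dm", frozenset(), "DM")

    fpg = record.fpg
    g2h = record.ogtt.glucose_2h if record.ogtt is not None else None
    if record.ogtt is None and (fpg is None or fpg < t.dm_fpg):
        raise MissingDataError(
            f"record {record.id!r}: OGTT absent without exemption")

    if (fpg is not None and fpg >= t.dm_fpg) \
            or (g2h is not None and g2h >= t.dm_2h) \
            or record.hba1c >= t.dm_hba1c:
        return GlycemicStatus("new_dm", frozenset(), "DM")

    criteria = set()
    if fpg is not None and fpg >= t.ifg_lower:
        criteria.add(CRIT_IFG)
    if g2h is not None and g2h >= t.igt_lower:
        criteria.add(CRIT_IGT)
    if record.hba1c >= t.hba1c_lower:
        criteria.add(CRIT_HBA1C)

    if CRIT_IFG in criteria and CRIT_IGT in criteria:
        subtype = "IFG_IGT"
    elif CRIT_IFG in criteria:
        subtype = "iIFG"
    elif CRIT_IGT in criteria:
        subtype = "iIGT"
    else:
        subtype = "NGT"

    if criteria:
        return GlycemicStatus("prediabetes", frozenset(criteria), subtype)
    return GlycemicStatus("ngt", frozenset(), "NGT")


def classify_cohort(cohort: CohortTable,
                    thresholds: GlycemicThresholds = DEFAULT_THRESHOLDS) -> pd.DataFrame:
    """Per-patient classification table: id, category, criteria, subtype."""
    rows = []
    for record in cohort:
        status = classify_patient(record, thresholds)
        rows.append({
            "id": record.id,
            "category": status.category,
            "criteria": ";".join(sorted(status.criteria)),
            "subtype": status.subtype,
        })
    return pd.DataFrame(rows, columns=["id", "category", "criteria", "subtype"])


def round_half_away(x: float) -> int:
    """Round to nearest integer, halves away from zero (report display rule)."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


@dataclass(frozen=True)
class PrevalenceSummary:
    """Category counts and percentages over one cohort (percentages unrounded)."""

    n_total: int
    n_known_dm: int
    n_new_dm: int
    n_prediabetes: int
    n_ngt: int
    pct_known_dm: float
    pct_new_dm: float
    pct_prediabetes: float
    pct_any_disturbance: float
    criterion_counts: dict = field(default_factory=dict)
    n_multi_criterion: int = 0

    def display_percentages(self) -> dict[str, int]:
        """Integer percentages for report display (half away from zero)."""
        return {
            "any_disturbance": round_half_away(self.pct_any_disturbance),
            "known_dm": round_half_away(self.pct_known_dm),
            "new_dm": round_half_away(self.pct_new_dm),
            "prediabetes": round_half_away(self.pct_prediabetes),
        }


def summarize_prevalence(cohort: CohortTable,
                         thresholds: GlycemicThresholds = DEFAULT_THRESHOLDS
                         ) -> PrevalenceSummary:
    """Counts and prevalence percentages of glycemic categories in a cohort."""
    if len(cohort) == 0:
        raise DomainError("empty cohort")
    statuses = [classify_patient(r, thresholds) for r in cohort]
    n = len(statuses)
    n_known = sum(s.category == "known_dm" for s in statuses)
    n_new = sum(s.category == "new_dm" for s in statuses)
    n_pre = sum(s.category == "prediabetes" for s in statuses)
    n_ngt = sum(s.category == "ngt" for s in statuses)
    crit_counts = {c: 0 for c in CRITERIA}
    n_multi = 0
    for s in statuses:
        if s.category == "prediabetes":
            for c in s.criteria:
                crit_counts[c] += 1
            if len(s.criteria) >= 2:
                n_multi += 1
    return PrevalenceSummary(
        n_total=n,
        n_known_dm=n_known,
        n_new_dm=n_new,
        n_prediabetes=n_pre,
        n_ngt=n_ngt,
        pct_known_dm=100.0 * n_known / n,
        pct_new_dm=100.0 * n_new / n,
        pct_prediabetes=100.0 * n_pre / n,
        pct_any_disturbance=100.0 * (n_known + n_new + n_pre) / n,
        criterion_counts=crit_counts,
        n_multi_criterion=n_multi,
    )


def subtype_table(cohort: CohortTable,
                  thresholds: GlycemicThresholds = DEFAULT_THRESHOLDS) -> dict[str, int]:
    """Glucose-tolerance subtype counts over the non-DM patients only."""
    counts = {s: 0 for s in SUBTYPES}
    for record in cohort:
        status = classify_patient(record, thresholds)
        if status.category in ("known_dm", "new_dm"):
            continue
        counts[status.subtype] += 1
    return counts


@dataclass(frozen=True)
class OverlapDecomposition:
    """Inclusion–exclusion decomposition of prediabetes criterion overlap."""

    n_single: int
    n_double: int
    n_triple: int
    excess: int
    witness: dict  # subset label -> patient count


def decompose_criterion_overlap(criterion_counts: dict[str, int],
                                n_patients: int,
                                n_multi: int) -> OverlapDecomposition:
    """Certify that a criterion multiset is realizable over unique patients.

    Given per-criterion assignment totals, the number of unique prediabetic
    patients and the number holding ≥2 criteria, solve (assuming exactly
    three criteria and multi = two or three criteria each):

        excess  = Σ counts − n_patients = n_double + 2·n_triple
        n_multi = n_double + n_triple

    and exhibit a non-negative per-subset witness, or raise
    :class:`DomainError` when none exists.
    """
    counts = {c: int(criterion_counts.get(c, 0)) for c in CRITERIA}
    total = sum(counts.values())
    excess = total - n_patients
    n_triple = excess - n_multi
    n_double = n_multi - n_triple
    n_single = n_patients - n_multi
    if min(n_single, n_double, n_triple) < 0:
        raise DomainError(
            f"infeasible overlap: singles={n_single}, doubles={n_double}, "
            f"triples={n_triple}")
    f, g, h = counts[CRIT_IFG], counts[CRIT_IGT], counts[CRIT_HBA1C]
    # enumerate double splits (pairs FG, FH, GH); small by construction
    for d_fg in range(n_double + 1):
        for d_fh in range(n_double - d_fg + 1):
            d_gh = n_double - d_fg - d_fh
            s_f = f - d_fg - d_fh - n_triple
            s_g = g - d_fg - d_gh - n_triple
            s_h = h - d_fh - d_gh - n_triple
            if min(s_f, s_g, s_h) >= 0 and s_f + s_g + s_h == n_single:
                witness = {
                    "IFG only": s_f, "IGT only": s_g, "HBA1C only": s_h,
                    "IFG+IGT": d_fg, "IFG+HBA1C": d_fh, "IGT+HBA1C": d_gh,
                    "IFG+IGT+HBA1C": n_triple,
                }
                return OverlapDecomposition(n_single, n_double, n_triple,
                                            excess, witness)
    raise DomainError("no non-negative per-subset assignment exists")
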