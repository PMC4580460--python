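"""ROC-based cutoff selection and relative-risk estimation.

The empirical ROC curve is evaluated at every distinct predictor value
with the orientation "score ≥ threshold ⇒ predicted positive"; AUC is the
trapezoidal area under the empirical curve, which equals the Mann–Whitney
concordance probability with ties counted one half. The operating point
maximizes the Youden index J = sensitivity + specificity − 1, ties broken
toward the lowest threshold (more patients flagged at risk).

Relative risk of a 2×2 table (a exposed cases, b exposed non-cases,
c unexposed cases, d unexposed non-cases) is (a/(a+b)) / (c/(c+d)) with a
Katz log-scale 95 % interval:

    exp( ln RR ± 1.96 · sqrt(1/a − 1/(a+b) + 1/c − 1/(c+d)) )

No continuity correction is applied; a zero case cell flags the result
undefined instead.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np

from .classify import GlycemicThresholds, DEFAULT_THRESHOLDS, classify_patient, \
    round_half_away
from .cohort import CohortTable
from .errors import DomainError

Z_95 = 1.959963984540054  # two-sided 95 % normal quantile


class ContingencyTable(NamedTuple):
    a: int  # exposed cases
    b: int  # exposed non-cases
    c: int  # unexposed cases
    d: int  # unexposed non-cases


@dataclass(frozen=True)
class ROCResult:
    thresholds: tuple[float, ...]        # ascending distinct predictor values
    sensitivity: tuple[float, ...]       # per threshold
    specificity: tuple[float, ...]       # per threshold
    auc: float
    optimal_cutoff: float
    optimal_sens: float
    optimal_spec: float


@dataclass(frozen=True)
class RiskResult:
    table: ContingencyTable
    rr: float | None
    ci_low: float | None
    ci_high: float | None
    flags: frozenset[str] = frozenset()


def roc_curve(scores: Sequence[float], labels: Sequence[int]) -> ROCResult:
    """Empirical ROC of a positively oriented continuous predictor."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise DomainError("scores and labels must be equal-length 1-d sequences")
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise DomainError("ROC requires at least one positive and one negative")

    thresholds = np.unique(scores)  # ascending
    pos_sorted = np.sort(scores[labels == 1])
    neg_sorted = np.sort(scores[labels == 0])
    # predicted positive: score >= t
    tp = n_pos - np.searchsorted(pos_sorted, thresholds, side="left")
    fp = n_neg - np.searchsorted(neg_sorted, thresholds, side="left")
    sens = tp / n_pos
    spec = 1.0 - fp / n_neg

    # trapezoid over the full curve: add the all-positive (t -> -inf) and
    # all-negative (t -> +inf) endpoints
    fpr = np.concatenate(([1.0], 1.0 - spec, [0.0]))[::-1]
    tpr = np.concatenate(([1.0], sens, [0.0]))[::-1]
    auc = float(np.trapezoid(tpr, fpr))

    youden = sens + spec - 1.0
    best = int(np.flatnonzero(youden == youden.max())[0])  # lowest threshold
    return ROCResult(
        thresholds=tuple(thresholds.tolist()),
        sensitivity=tuple(sens.tolist()),
        specificity=tuple(spec.tolist()),
        auc=auc,
        optimal_cutoff=float(thresholds[best]),
        optimal_sens=float(sens[best]),
        optimal_spec=float(spec[best]),
    )


def reconstruct_2x2(sens: float, spec: float, n_pos: int, n_neg: int) -> ContingencyTable:
    """Rebuild integer 2×2 counts from printed sensitivity/specificity.

    Rounding is half away from zero. Used to recover a published table from
    reported operating characteristics and group sizes.
    """
    if not (0 <= sens <= 1 and 0 <= spec <= 1):
        raise DomainError("sens/spec must lie in [0, 1]")
    if n_pos <= 0 or n_neg <= 0:
        raise DomainError("group sizes must be positive")
    a = round_half_away(sens * n_pos)
    d = round_half_away(spec * n_neg)
    return ContingencyTable(a=a, b=n_neg - d, c=n_pos - a, d=d)


def relative_risk(table: ContingencyTable | Sequence[int]) -> RiskResult:
    """Relative risk with Katz log-scale 95 % CI for a 2×2 table."""
    a, b, c, d = (int(x) for x in table)
    if min(a, b, c, d) < 0:
        raise DomainError("negative cell count")
    if a + b == 0 or c + d == 0:
        raise DomainError("empty exposure margin")
    tab = ContingencyTable(a, b, c, d)
    if a == 0 or c == 0:
        return RiskResult(tab, None, None, None, frozenset({"undefined"}))
    rr = (a / (a + b)) / (c / (c + d))
    se = math.sqrt(1 / a - 1 / (a + b) + 1 / c - 1 / (c + d))
    log_rr = math.log(rr)
    return RiskResult(
        tab, rr,
        math.exp(log_rr - Z_95 * se),
        math.exp(log_rr + Z_95 * se),
    )


def stratify(cohort: CohortTable, predictor: str,
             thresholds: GlycemicThresholds = DEFAULT_THRESHOLDS,
             cutoff_override: float | None = None) -> tuple[ROCResult, RiskResult]:
    """ROC + relative risk of prediabetes for a continuous predictor.

    Restricted to patients without manifest diabetes (known or newly
    diagnosed); prediabetes is the positive label and exposure is
    predictor ≥ cutoff.
    """
    if predictor not in ("age", "bmi"):
        raise DomainError(f"unsupported predictor {predictor!r}")
    scores, labels = [], []
    for record in cohort:
        status = classify_patient(record, thresholds)
        if status.category in ("known_dm", "new_dm"):
            continue
        scores.append(getattr(record, predictor))
        labels.append(1 if status.category == "prediabetes" else 0)
    roc = roc_curve(scores, labels)
    cutoff = roc.optimal_cutoff if cutoff_override is None else float(cutoff_override)
    scores_arr = np.asarray(scores)
    labels_arr = np.asarray(labels)
    exposed = scores_arr >= cutoff
    table = ContingencyTable(
        a=int((exposed & (labels_arr == 1)).sum()),
        b=int((exposed & (labels_arr == 0)).sum()),
        c=int((~exposed & (labels_arr == 1)).sum()),
        d=int((~exposed & (labels_arr == 0)).sum()),
    )
    if table.a + table.b == 0 or table.c + table.d == 0:
        # cutoff at the extreme of the score range: everyone (or no one)
        # exposed, relative risk undefined rather than an error
        return roc, RiskResult(table, None, None, None,
                               frozenset({"degenerate_margin"}))
    return roc, relative_risk(table)
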