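"""Covariate-adjusted linear models on log-transformed indices.

Each index (right-skewed by construction) is natural-log transformed and
z-scored; continuous covariates are z-scored and binary covariates enter
as 0/1 indicators, so reported slopes are standardized coefficients
(|beta| < 1 for non-degenerate data). Records with an undefined or
non-positive insulinogenic index are excluded from fits on IGI or the
disposition index and counted, never imputed. Patients with known
diabetes carry no OGTT and therefore never enter these models.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.linalg
import statsmodels.api as sm

from .classify import GlycemicThresholds, DEFAULT_THRESHOLDS, classify_patient
from .cohort import CohortTable
from .errors import CollinearityError, DomainError
from .indices import FLAG_IGI_NEGATIVE, FLAG_IGI_UNDEFINED, compute_indices

OUTCOMES = ("homa_ir", "matsuda_isi", "igi", "disposition")

#: default adjustment/factor set mirroring the joint model of the study
DEFAULT_COVARIATES = ("sex", "age", "bmi", "fh_dm", "modality",
                      "waiting_time", "prior_tx")

_BINARY = {"sex", "fh_dm", "modality", "prior_tx"}


@dataclass(frozen=True)
class Term:
    name: str
    beta: float
    p: float
    ci_low: float
    ci_high: float


@dataclass(frozen=True)
class AdjustedFit:
    outcome: str
    terms: tuple[Term, ...]
    n_used: int
    n_excluded: int
    transform: str = "log"

    def term(self, name: str) -> Term:
        for t in self.terms:
            if t.name == name:
                return t
        raise KeyError(name)


def _design_frame(cohort: CohortTable, outcome: str,
                  thresholds: GlycemicThresholds) -> tuple[pd.DataFrame, int]:
    """Merged covariate + index frame for modelable patients.

    Returns the usable frame and the count of records excluded for a
    missing OGTT or a flagged (undefined/non-positive) IGI when the
    outcome depends on it.
    """
    idx = compute_indices(cohort).set_index("id")
    rows, n_excluded = [], 0
    for record in cohort:
        if record.known_dm != "none" or record.ogtt is None:
            n_excluded += 1
            continue
        flags = set(filter(None, str(idx.loc[record.id, "flags"]).split(";")))
        value = idx.loc[record.id, outcome]
        if outcome in ("igi", "disposition") and \
                flags & {FLAG_IGI_NEGATIVE, FLAG_IGI_UNDEFINED}:
            n_excluded += 1
            continue
        if value is None or not np.isfinite(value) or value <= 0:
            n_excluded += 1
            continue
        status = classify_patient(record, thresholds)
        rows.append({
            "id": record.id,
            "y": float(value),
            "sex": 1.0 if record.sex == "m" else 0.0,
            "age": record.age,
            "bmi": record.bmi,
            "fh_dm": 1.0 if record.family_history_dm else 0.0,
            "modality": 1.0 if record.dialysis_modality != "HD" else 0.0,
            "waiting_time": record.waiting_time,
            "prior_tx": 1.0 if record.prior_transplants > 0 else 0.0,
            "subtype": status.subtype,
        })
    return pd.DataFrame(rows), n_excluded


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=1)
    if sd == 0:
        raise CollinearityError([], "constant column cannot be standardized")
    return (x - x.mean()) / sd


def _check_rank(X: pd.DataFrame) -> None:
    mat = np.column_stack([np.ones(len(X)), X.to_numpy(float)])
    if np.linalg.matrix_rank(mat) < mat.shape[1]:
        _, r, piv = scipy.linalg.qr(mat, pivoting=True)
        diag = np.abs(np.diag(r))
        tol = diag.max() * max(mat.shape) * np.finfo(float).eps
        bad = [piv[i] for i in range(len(diag)) if diag[i] < tol] + \
              list(piv[len(diag):])
        names = ["const"] + list(X.columns)
        raise CollinearityError([names[i] for i in sorted(bad)])


def fit_adjusted(cohort: CohortTable, outcome: str,
                 covariates: tuple[str, ...] = DEFAULT_COVARIATES,
                 thresholds: GlycemicThresholds = DEFAULT_THRESHOLDS) -> AdjustedFit:
    """OLS of a log index on standardized covariates, one joint model."""
    if outcome not in OUTCOMES:
        raise DomainError(f"unknown outcome {outcome!r}")
    frame, n_excluded = _design_frame(cohort, outcome, thresholds)
    if len(frame) < len(covariates) + 2:
        raise DomainError(
            f"{len(frame)} usable records, need >= {len(covariates) + 2}")
    y = _zscore(np.log(frame["y"].to_numpy()))
    X = pd.DataFrame(index=frame.index)
    for cov in covariates:
        col = frame[cov].to_numpy(float)
        X[cov] = col if cov in _BINARY else _zscore(col)
    _check_rank(X)
    res = sm.OLS(y, sm.add_constant(X)).fit()
    ci = res.conf_int(alpha=0.05)
    terms = tuple(
        Term(name=cov, beta=float(res.params[cov]), p=float(res.pvalues[cov]),
             ci_low=float(ci.loc[cov, 0]), ci_high=float(ci.loc[cov, 1]))
        for cov in covariates
    )
    return AdjustedFit(outcome=outcome, terms=terms, n_used=len(frame),
                       n_excluded=n_excluded, transform="log")


def group_contrast(cohort: CohortTable, outcome: str,
                   adjust_for: tuple[str, ...] = ("sex", "age", "bmi"),
                   thresholds: GlycemicThresholds = DEFAULT_THRESHOLDS) -> float:
    """Adjusted overall group effect of glucose-tolerance subtype.

    Fits OLS of the log index on subtype indicators plus adjustment
    covariates and returns the p-value of the F-test on the indicator
    block. Empty subtype levels are dropped with a warning.
    """
    if outcome not in OUTCOMES:
        raise DomainError(f"unknown outcome {outcome!r}")
    frame, _ = _design_frame(cohort, outcome, thresholds)
    levels = [s for s in ("NGT", "iIFG", "iIGT", "IFG_IGT")
              if (frame["subtype"] == s).any()]
    dropped = set(("NGT", "iIFG", "iIGT", "IFG_IGT")) - set(levels)
    if dropped:
        warnings.warn(f"empty subtype level(s) dropped: {sorted(dropped)}")
    if len(levels) < 2:
        raise DomainError("group contrast requires at least two subtype levels")
    if len(frame) < len(levels) + len(adjust_for) + 2:
        raise DomainError("too few usable records for the group contrast")
    y = _zscore(np.log(frame["y"].to_numpy()))
    X = pd.DataFrame(index=frame.index)
    for level in levels[1:]:  # first level is the reference
        X[f"grp_{level}"] = (frame["subtype"] == level).astype(float)
    for cov in adjust_for:
        col = frame[cov].to_numpy(float)
        X[cov] = col if cov in _BINARY else _zscore(col)
    _check_rank(X)
    res = sm.OLS(y, sm.add_constant(X)).fit()
    contrast = [f"grp_{level} = 0" for level in levels[1:]]
    ftest = res.f_test(", ".join(contrast))
    return float(ftest.pvalue)


def fit_all_outcomes(cohort: CohortTable,
                     covariates: tuple[str, ...] = DEFAULT_COVARIATES,
                     thresholds: GlycemicThresholds = DEFAULT_THRESHOLDS
                     ) -> pd.DataFrame:
    """Long-format fit report over all four indices (one joint model each)."""
    rows = []
    for outcome in OUTCOMES:
        fit = fit_adjusted(cohort, outcome, covariates, thresholds)
        for term in fit.terms:
            rows.append({
                "outcome": outcome, "term": term.name, "beta": term.beta,
                "p": term.p, "ci_low": term.ci_low, "ci_high": term.ci_high,
                "n_used": fit.n_used, "transform": fit.transform,
            })
    return pd.DataFrame(rows)
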