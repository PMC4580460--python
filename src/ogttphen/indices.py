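"""OGTT-derived insulin sensitivity and secretion indices.

Four per-patient surrogates computed from fasting and post-load glucose
and insulin:

* HOMA-IR        — fasting glucose [mmol/l] × fasting insulin [µU/ml] / 22.5;
                   a marker of (hepatic) insulin resistance.
* Matsuda ISI    — 10000 / sqrt(FPG · FPI · meanG · meanI) with glucose on
                   the mg/dl scale; whole-body insulin sensitivity from all
                   five OGTT time points (arithmetic means, t = 0 included).
* IGI            — (Ins30 − Ins0) / (Glc30 − Glc0); early-phase insulin
                   secretion, µU/ml per mmol/l.
* disposition    — Matsuda ISI × IGI; beta-cell output relative to the
                   prevailing insulin sensitivity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .cohort import MGDL_PER_MMOL, CohortTable, OGTTSeries
from .errors import DomainError, MissingDataError

#: quality flags attached to an IndexSet
FLAG_IGI_UNDEFINED = "igi_undefined"
FLAG_IGI_NEGATIVE = "igi_negative"
FLAG_NO_OGTT = "no_ogtt"


@dataclass(frozen=True)
class IndexSet:
    """The four indices for one patient; absent values are ``None``."""

    homa_ir: float | None
    matsuda_isi: float | None
    igi: float | None
    disposition: float | None
    flags: frozenset[str] = frozenset()


def homa_ir(fpg: float, fpi: float) -> float:
    """HOMA-IR from fasting glucose (mmol/l) and fasting insulin (µU/ml)."""
    if fpg <= 0 or fpi <= 0:
        raise DomainError(f"HOMA-IR requires positive inputs, got ({fpg}, {fpi})")
    return fpg * fpi / 22.5


def matsuda_isi(series: OGTTSeries | None) -> float:
    """Matsuda whole-body insulin sensitivity index.

    Glucose is converted to mg/dl (× 18.016) before evaluation; the means
    are plain arithmetic means over all five sampled points.
    """
    if series is None:
        raise MissingDataError("Matsuda ISI requires a complete OGTT series")
    fpg_mgdl = series.fpg * MGDL_PER_MMOL
    mean_g_mgdl = series.mean_glucose * MGDL_PER_MMOL
    product = fpg_mgdl * series.fpi * mean_g_mgdl * series.mean_insulin
    if product <= 0:
        raise DomainError("Matsuda ISI undefined for zero insulin")
    return 10000.0 / math.sqrt(product)


def insulinogenic_index(series: OGTTSeries | None) -> tuple[float | None, frozenset[str]]:
    """Insulinogenic index with quality flags.

    Returns ``(value, flags)``. A zero glucose increment yields
    ``(None, {igi_undefined})``; a non-positive ratio is retained with the
    ``igi_negative`` flag so downstream stages can exclude it explicitly.
    """
    if series is None:
        raise MissingDataError("insulinogenic index requires a complete OGTT series")
    d_glc = series.glucose[1] - series.glucose[0]
    if d_glc == 0:
        return None, frozenset({FLAG_IGI_UNDEFINED})
    value = (series.insulin[1] - series.insulin[0]) / d_glc
    if value <= 0:
        return value, frozenset({FLAG_IGI_NEGATIVE})
    return value, frozenset()


def disposition_index(matsuda: float | None, igi: float | None) -> float | None:
    """Product of Matsuda ISI and IGI; absent if either factor is absent."""
    if matsuda is None or igi is None:
        return None
    return matsuda * igi


def compute_index_set(series: OGTTSeries | None) -> IndexSet:
    """All four indices for one OGTT; an absent series yields an empty set."""
    if series is None:
        return IndexSet(None, None, None, None, frozenset({FLAG_NO_OGTT}))
    h = homa_ir(series.fpg, series.fpi)
    m = matsuda_isi(series)
    igi, flags = insulinogenic_index(series)
    disp = disposition_index(m, igi)
    return IndexSet(h, m, igi, disp, flags)


def compute_indices(cohort: CohortTable) -> pd.DataFrame:
    """Per-patient index table for a cohort (one row per record, in order).

    Patients without a complete OGTT get an all-absent row flagged
    ``no_ogtt``; absences are data, not errors.
    """
    rows = []
    for record in cohort:
        idx = compute_index_set(record.ogtt)
        rows.append(
            {
                "id": record.id,
                "homa_ir": idx.homa_ir,
                "matsuda_isi": idx.matsuda_isi,
                "igi": idx.igi,
                "disposition": idx.disposition,
                "flags": ";".join(sorted(idx.flags)),
            }
        )
    return pd.DataFrame(rows, columns=["id", "homa_ir", "matsuda_isi", "igi",
                                       "disposition", "flags"])
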