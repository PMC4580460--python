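"""Cohort domain types, unit conventions and delimited-text I/O.

Canonical internal units are mmol/l for glucose and µU/ml for insulin.
Glucose may arrive in mg/dl (divided by 18.016) and insulin in pmol/l
(divided by 6.0); the unit labels are declared in a :class:`UnitConfig`,
never inferred from the data.
"""

from __future__ import annotations

import dataclasses
import math
import tomllib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import pandas as pd

from .errors import RowValidationError, SchemaError, UnitConfigError

#: mg/dl per mmol/l of glucose (molar mass 180.16 g/mol).
MGDL_PER_MMOL = 18.016
#: pmol/l per µU/ml of insulin.
PMOL_PER_UU = 6.0

#: Fixed OGTT sampling grid in minutes.
OGTT_TIMES: tuple[int, ...] = (0, 30, 60, 90, 120)

#: Fixed cohort CSV column order.
COHORT_COLUMNS: tuple[str, ...] = (
    "id", "sex", "age", "bmi", "modality", "waiting_time", "fh_dm",
    "prior_tx", "known_dm", "hba1c",
    "glc_0", "glc_30", "glc_60", "glc_90", "glc_120",
    "ins_0", "ins_30", "ins_60", "ins_90", "ins_120",
)

SEXES = ("f", "m")
MODALITIES = ("HD", "PD", "preemptive")
KNOWN_DM = ("none", "type1", "type2")

_TRUE = {"1", "true", "t", "yes", "y"}
_FALSE = {"0", "false", "f", "no", "n"}


def glucose_mgdl_to_mmol(value: float) -> float:
    return value / MGDL_PER_MMOL


def glucose_mmol_to_mgdl(value: float) -> float:
    return value * MGDL_PER_MMOL


def insulin_pmol_to_uu(value: float) -> float:
    return value / PMOL_PER_UU


@dataclass(frozen=True)
class UnitConfig:
    """Measurement units of the glucose and insulin columns of an input file."""

    glucose_unit: str = "mmol_l"
    insulin_unit: str = "uU_ml"

    def __post_init__(self):
        if self.glucose_unit not in ("mmol_l", "mg_dl"):
            raise UnitConfigError(f"unknown glucose unit {self.glucose_unit!r}")
        if self.insulin_unit not in ("uU_ml", "pmol_l"):
            raise UnitConfigError(f"unknown insulin unit {self.insulin_unit!r}")

    @classmethod
    def from_file(cls, path: str | Path) -> "UnitConfig":
        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        keys = set(data) - {"glucose_unit", "insulin_unit"}
        if keys:
            raise UnitConfigError(f"unknown unit-config keys: {sorted(keys)}")
        return cls(**data)

    def glucose_to_canonical(self, value: float) -> float:
        return glucose_mgdl_to_mmol(value) if self.glucose_unit == "mg_dl" else value

    def insulin_to_canonical(self, value: float) -> float:
        return insulin_pmol_to_uu(value) if self.insulin_unit == "pmol_l" else value


@dataclass(frozen=True)
class OGTTSeries:
    """Glucose (mmol/l) and insulin (µU/ml) on the fixed 0–120 min grid."""

    glucose: tuple[float, float, float, float, float]
    insulin: tuple[float, float, float, float, float]

    times: tuple[int, ...] = field(default=OGTT_TIMES, init=False, repr=False)

    def __post_init__(self):
        glucose = tuple(float(g) for g in self.glucose)
        insulin = tuple(float(i) for i in self.insulin)
        if len(glucose) != len(OGTT_TIMES) or len(insulin) != len(OGTT_TIMES):
            raise ValueError("OGTT series requires exactly 5 time points")
        for g in glucose:
            if not math.isfinite(g) or not 0 < g < 50:
                raise ValueError(f"glucose {g} outside (0, 50) mmol/l")
        for i in insulin:
            if not math.isfinite(i) or i < 0:
                raise ValueError(f"insulin {i} negative or non-finite")
        object.__setattr__(self, "glucose", glucose)
        object.__setattr__(self, "insulin", insulin)

    @property
    def fpg(self) -> float:
        """Fasting plasma glucose, mmol/l (t = 0)."""
        return self.glucose[0]

    @property
    def fpi(self) -> float:
        """Fasting plasma insulin, µU/ml (t = 0)."""
        return self.insulin[0]

    @property
    def glucose_2h(self) -> float:
        return self.glucose[-1]

    @property
    def mean_glucose(self) -> float:
        return sum(self.glucose) / len(self.glucose)

    @property
    def mean_insulin(self) -> float:
        return sum(self.insulin) / len(self.insulin)


@dataclass(frozen=True)
class PatientRecord:
    """One waiting-list candidate: clinical covariates, HbA1c and optional OGTT.

    ``fpg_screen`` holds a fasting glucose recorded without a full OGTT
    (the OGTT-contraindication pathway: manifest hyperglycemia at
    presentation). ``ogtt_partial`` marks records whose OGTT had some but
    not all time points; such records are retained but excluded from
    OGTT-derived computations downstream.
    """

    id: str
    sex: str
    age: float
    bmi: float
    dialysis_modality: str
    waiting_time: float
    family_history_dm: bool
    prior_transplants: int
    known_dm: str
    hba1c: float
    ogtt: OGTTSeries | None = None
    fpg_screen: float | None = None
    ogtt_partial: bool = False

    def __post_init__(self):
        def bad(field_name, msg):
            raise RowValidationError(str(self.id), field_name, msg)

        if not str(self.id):
            bad("id", "empty id")
        if self.sex not in SEXES:
            bad("sex", f"{self.sex!r} not in {SEXES}")
        if not 18 <= self.age <= 100:
            bad("age", f"{self.age} outside [18, 100] years")
        if not 10 <= self.bmi <= 60:
            bad("bmi", f"{self.bmi} outside [10, 60] kg/m²")
        if self.dialysis_modality not in MODALITIES:
            bad("modality", f"{self.dialysis_modality!r} not in {MODALITIES}")
        if self.waiting_time < 0:
            bad("waiting_time", "negative waiting time")
        if self.prior_transplants < 0 or int(self.prior_transplants) != self.prior_transplants:
            bad("prior_tx", "must be a non-negative integer")
        if self.known_dm not in KNOWN_DM:
            bad("known_dm", f"{self.known_dm!r} not in {KNOWN_DM}")
        if not 3 <= self.hba1c <= 20:
            bad("hba1c", f"{self.hba1c} outside [3, 20] %")
        if self.ogtt is None and not self.ogtt_partial and self.known_dm == "none":
            if self.fpg_screen is None or self.fpg_screen < 7.0:
                bad("ogtt", "OGTT absent without exemption "
                            "(known DM or fasting glucose >= 7 mmol/l)")

    @property
    def fpg(self) -> float | None:
        """Fasting glucose from the OGTT, or the screening value if no OGTT."""
        if self.ogtt is not None:
            return self.ogtt.fpg
        return self.fpg_screen


@dataclass(frozen=True)
class CohortTable:
    """Ordered, id-unique collection of patient records."""

    records: tuple[PatientRecord, ...]
    provenance: str = ""

    def __post_init__(self):
        records = tuple(self.records)
        if not records:
            raise ValueError("empty cohort")
        ids = [r.id for r in records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate patient ids: {dupes}")
        object.__setattr__(self, "records", records)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[PatientRecord]:
        return iter(self.records)

    def to_dataframe(self) -> pd.DataFrame:
        """Covariate view (no OGTT columns) used by the regression stage."""
        return pd.DataFrame(
            {
                "id": [r.id for r in self.records],
                "sex": [r.sex for r in self.records],
                "age": [r.age for r in self.records],
                "bmi": [r.bmi for r in self.records],
                "modality": [r.dialysis_modality for r in self.records],
                "waiting_time": [r.waiting_time for r in self.records],
                "fh_dm": [r.family_history_dm for r in self.records],
                "prior_tx": [r.prior_transplants for r in self.records],
                "known_dm": [r.known_dm for r in self.records],
                "hba1c": [r.hba1c for r in self.records],
            }
        )


def _parse_bool(raw: str, patient_id: str, field_name: str) -> bool:
    token = raw.strip().lower()
    if token in _TRUE:
        return True
    if token in _FALSE:
        return False
    raise RowValidationError(patient_id, field_name, f"cannot parse boolean {raw!r}")


def _parse_sex(raw: str, patient_id: str) -> str:
    token = raw.strip().lower()
    if token in ("f", "female"):
        return "f"
    if token in ("m", "male"):
        return "m"
    raise RowValidationError(patient_id, "sex", f"cannot parse sex {raw!r}")


def _parse_float(raw, patient_id: str, field_name: str) -> float:
    try:
        return float(raw)
    except (TypeError, ValueError):
        raise RowValidationError(patient_id, field_name, f"cannot parse number {raw!r}")


def read_cohort(path: str | Path, config: UnitConfig | None = None) -> CohortTable:
    """Read a cohort CSV, validate every row and convert to canonical units.

    Raises :class:`SchemaError` if the header does not carry exactly the
    declared columns, and :class:`RowValidationError` (with patient id and
    field) on the first invalid row. Row order is preserved.
    """
    config = config or UnitConfig()
    path = Path(path)
    try:
        frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise SchemaError(f"{path}: empty file, no header row")
    missing = [c for c in COHORT_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    extra = [c for c in frame.columns if c not in COHORT_COLUMNS]
    if extra:
        raise SchemaError(f"{path}: unexpected column(s) {extra}")

    records = []
    for row in frame.itertuples(index=False):
        row = dict(zip(frame.columns, row))
        pid = str(row["id"]).strip()
        known_dm = str(row["known_dm"]).strip().lower() or "none"
        if known_dm not in KNOWN_DM:
            raise RowValidationError(pid, "known_dm", f"unknown value {row['known_dm']!r}")

        glc_cells = [str(row[f"glc_{t}"]).strip() for t in OGTT_TIMES]
        ins_cells = [str(row[f"ins_{t}"]).strip() for t in OGTT_TIMES]
        present = [c != "" for c in glc_cells + ins_cells]
        ogtt = None
        fpg_screen = None
        partial = False
        if all(present):
            glucose = tuple(
                config.glucose_to_canonical(_parse_float(c, pid, f"glc_{t}"))
                for c, t in zip(glc_cells, OGTT_TIMES)
            )
            insulin = tuple(
                config.insulin_to_canonical(_parse_float(c, pid, f"ins_{t}"))
                for c, t in zip(ins_cells, OGTT_TIMES)
            )
            try:
                ogtt = OGTTSeries(glucose, insulin)
            except ValueError as exc:
                raise RowValidationError(pid, "ogtt", str(exc))
        elif any(present):
            if glc_cells[0] != "":
                fpg_screen = config.glucose_to_canonical(
                    _parse_float(glc_cells[0], pid, "glc_0"))
            # fasting glucose alone is the contraindication pathway, not a
            # broken series; anything else is a partial OGTT
            partial = any(present[1:5]) or any(present[5:])

        record = PatientRecord(
            id=pid,
            sex=_parse_sex(str(row["sex"]), pid),
            age=_parse_float(row["age"], pid, "age"),
            bmi=_parse_float(row["bmi"], pid, "bmi"),
            dialysis_modality=str(row["modality"]).strip(),
            waiting_time=_parse_float(row["waiting_time"], pid, "waiting_time"),
            family_history_dm=_parse_bool(str(row["fh_dm"]), pid, "fh_dm"),
            prior_transplants=int(_parse_float(row["prior_tx"], pid, "prior_tx")),
            known_dm=known_dm,
            hba1c=_parse_float(row["hba1c"], pid, "hba1c"),
            ogtt=ogtt,
            fpg_screen=fpg_screen,
            ogtt_partial=partial,
        )
        records.append(record)
    return CohortTable(tuple(records), provenance=str(path))


def write_cohort(cohort: CohortTable, path: str | Path) -> None:
    """Write a cohort CSV in canonical units; absent values become empty cells."""
    rows = []
    for r in cohort:
        row = {
            "id": r.id,
            "sex": r.sex,
            "age": r.age,
            "bmi": r.bmi,
            "modality": r.dialysis_modality,
            "waiting_time": r.waiting_time,
            "fh_dm": int(r.family_history_dm),
            "prior_tx": r.prior_transplants,
            "known_dm": r.known_dm,
            "hba1c": r.hba1c,
        }
        for t in OGTT_TIMES:
            row[f"glc_{t}"] = ""
            row[f"ins_{t}"] = ""
        if r.ogtt is not None:
            for t, g, i in zip(OGTT_TIMES, r.ogtt.glucose, r.ogtt.insulin):
                row[f"glc_{t}"] = repr(g)
                row[f"ins_{t}"] = repr(i)
        elif r.fpg_screen is not None:
            row["glc_0"] = repr(r.fpg_screen)
        rows.append(row)
    frame = pd.DataFrame(rows, columns=list(COHORT_COLUMNS))
    frame.to_csv(path, index=False)
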