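"""Synthetic waiting-list cohort generator.

Emulates a 138-patient kidney-transplant waiting-list cohort: covariate
marginals (age median ~51 on [19, 76], BMI median ~25.6 on [16.7, 38.2],
sex / dialysis-modality / family-history frequencies), a ~22 % stratum of
known diabetes without OGTT, and — through a latent two-factor physiology —
the structural dependencies the downstream analysis is meant to detect:
BMI depresses insulin sensitivity and age depresses insulin secretion.

Each patient carries a latent whole-body insulin sensitivity S and
secretory capacity B (both log-linear in the covariates, with partial
hyperinsulinemic compensation of low S by B). The OGTT curve is produced
by a small discrete glucose–insulin response model on the 0–120 min grid:
fasting glucose and insulin are decreasing/increasing maps of S, the
glucose load appears as an excess pool that decays each 30-min step at a
fractional rate proportional to S times the prevailing insulin, and
insulin responds linearly (slope B) to the glucose excess. Multiplicative
assay noise is applied to every measurement. HbA1c is an affine map of
mean OGTT glucose plus noise. The generator is a structural test-bed, not
a validated physiological simulator.

Calibration constants (basal maps, dose, clearance, HbA1c map) are fixed
package defaults tuned once so that ADA classification of the generated
patients reproduces the target prevalence mix at large n.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np

from .classify import DEFAULT_THRESHOLDS, classify_patient, \
    decompose_criterion_overlap
from .cohort import CohortTable, OGTTSeries, PatientRecord
from .errors import ParameterError


@dataclass(frozen=True)
class GeneratorParams:
    """Study-condition parameters (first block) and frozen calibration
    constants (second block) of the cohort generator."""

    n: int = 138
    seed: int = 0
    frac_known_dm: float = 30 / 138
    frac_type1: float = 14 / 30           # of the known-DM stratum
    target_prediabetes_frac: float = 42 / 138

    age_range: tuple[float, float] = (19.0, 76.0)
    age_beta: tuple[float, float] = (2.6, 2.1)   # median ~0.561 -> ~51 yrs
    bmi_range: tuple[float, float] = (16.7, 38.2)
    bmi_log_median: float = math.log(25.6)
    bmi_log_sd: float = 0.16
    p_male: float = 80 / 138
    modality_probs: tuple[float, float, float] = (114 / 138, 22 / 138, 2 / 138)
    p_family_history: float = 49 / 138
    p_retx: float = 29 / 138
    waiting_shape: float = 1.7
    waiting_scale: float = 2.9
    waiting_max: float = 13.3

    sens_bmi_slope: float = -0.045        # d ln S / d BMI  (<= 0)
    secr_age_slope: float = -0.013        # d ln B / d age  (<= 0)
    gamma_comp: float = 0.5               # B ~ S^-gamma partial compensation
    noise_sd_sens: float = 0.45
    noise_sd_secr: float = 0.45
    assay_cv: float = 0.04

    # ---- frozen calibration constants ----
    basal_insulin_ref: float = 2.5        # µU/ml at S = 1
    basal_insulin_exp: float = 0.8        # I_basal = ref * S^-exp
    fasting_glucose_ref: float = 4.9      # mmol/l at S = 1
    fasting_glucose_exp: float = 0.15     # G_basal = ref * S^-exp
    fasting_glucose_sd: float = 0.05     # lognormal sd of G_basal
    secretion_ref: float = 20.0           # µU/ml per mmol/l excess at B = 1
    #: first-phase dominance of the insulin response: relative weight of the
    #: secretory response at 30/60/90/120 min (early spike, faster decay
    #: than the glucose excess itself)
    insulin_phase_weights: tuple[float, float, float, float] = (1.0, 0.55, 0.35, 0.25)
    glucose_dose: float = 5.6             # mmol/l excess appearing at t = 0+
    clearance_rate: float = 0.007         # per µU/ml per 30-min step at S = 1
    hba1c_intercept: float = 3.34         # %  (affine map of mean glucose)
    hba1c_slope: float = 0.30             # % per mmol/l mean OGTT glucose
    hba1c_sd: float = 0.18
    hba1c_range: tuple[float, float] = (4.3, 8.6)
    known_dm_hba1c: tuple[float, float] = (6.9, 0.8)  # mean, sd (shifted band)

    def __post_init__(self):
        if self.n < 10:
            raise ParameterError("n must be >= 10")
        for name in ("frac_known_dm", "frac_type1", "target_prediabetes_frac",
                     "p_male", "p_family_history", "p_retx"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ParameterError(f"{name}={v} outside [0, 1]")
        if self.frac_known_dm + self.target_prediabetes_frac > 1:
            raise ParameterError("category fractions exceed 1")
        if self.sens_bmi_slope > 0 or self.secr_age_slope > 0:
            raise ParameterError("structural slopes must be <= 0")
        if not 0 <= self.gamma_comp < 1:
            raise ParameterError("gamma_comp must lie in [0, 1)")
        if abs(sum(self.modality_probs) - 1) > 1e-9:
            raise ParameterError("modality probabilities must sum to 1")


def simulate_ogtt_response(S: np.ndarray, B: np.ndarray,
                           G0: np.ndarray, I_basal: np.ndarray,
                           params: GeneratorParams) -> tuple[np.ndarray, np.ndarray]:
    """Noise-free OGTT glucose/insulin curves for latent (S, B) patients.

    Vectorized over patients; returns (n, 5) arrays on the fixed grid.
    """
    S, B, G0, I_basal = (np.atleast_1d(np.asarray(a, float))
                         for a in (S, B, G0, I_basal))
    n = S.shape[0]
    G = np.empty((n, 5))
    I = np.empty((n, 5))
    G[:, 0] = G0
    I[:, 0] = I_basal
    excess = np.full(n, params.glucose_dose)
    w = (1.0,) + tuple(params.insulin_phase_weights)
    for k in range(1, 5):
        i_prev = I[:, k - 1]
        excess = excess * np.exp(-params.clearance_rate * S * i_prev)
        G[:, k] = G0 + excess
        I[:, k] = I_basal + params.secretion_ref * B * w[k] * excess
    return G, I


def generate_cohort(params: GeneratorParams | None = None, *,
                    provenance: str = "synthetic") -> CohortTable:
    """Draw one synthetic cohort; deterministic given ``params.seed``."""
    p = params or GeneratorParams()
    rng = np.random.default_rng(p.seed)
    n = p.n

    lo, hi = p.age_range
    age = np.round(lo + (hi - lo) * rng.beta(*p.age_beta, size=n), 1)
    bmi = np.exp(rng.normal(p.bmi_log_median, p.bmi_log_sd, size=n))
    bmi = np.round(np.clip(bmi, *p.bmi_range), 1)
    sex = np.where(rng.random(n) < p.p_male, "m", "f")
    modality = rng.choice(["HD", "PD", "preemptive"], size=n, p=p.modality_probs)
    fh = rng.random(n) < p.p_family_history
    retx = (rng.random(n) < p.p_retx).astype(int)
    waiting = np.round(np.clip(
        rng.gamma(p.waiting_shape, p.waiting_scale, size=n), 0, p.waiting_max), 1)

    ln_s = p.sens_bmi_slope * (bmi - 25.6) + rng.normal(0, p.noise_sd_sens, n)
    ln_b = p.secr_age_slope * (age - 51.0) - p.gamma_comp * ln_s \
        + rng.normal(0, p.noise_sd_secr, n)
    S = np.exp(ln_s)
    B = np.exp(ln_b)

    G0 = p.fasting_glucose_ref * S ** (-p.fasting_glucose_exp) \
        * np.exp(rng.normal(0, p.fasting_glucose_sd, n))
    I_basal = p.basal_insulin_ref * S ** (-p.basal_insulin_exp)
    G, I = simulate_ogtt_response(S, B, G0, I_basal, p)

    # multiplicative assay noise on every measurement
    G_meas = G * np.exp(rng.normal(0, p.assay_cv, (n, 5)))
    I_meas = I * np.exp(rng.normal(0, p.assay_cv, (n, 5)))
    G_meas = np.clip(G_meas, 0.1, 49.9)

    hba1c = p.hba1c_intercept + p.hba1c_slope * G.mean(axis=1) \
        + rng.normal(0, p.hba1c_sd, n)
    hba1c = np.round(np.clip(hba1c, *p.hba1c_range), 1)

    n_known = int(round(p.frac_known_dm * n))
    known_idx = np.sort(rng.choice(n, size=n_known, replace=False))
    known_mask = np.zeros(n, dtype=bool)
    known_mask[known_idx] = True
    n_type1 = int(round(p.frac_type1 * n_known))
    dm_type = np.array(["type1"] * n_type1 + ["type2"] * (n_known - n_type1))
    mean_k, sd_k = p.known_dm_hba1c
    hba1c_known = np.round(np.clip(
        rng.normal(mean_k, sd_k, n_known), 5.0, p.hba1c_range[1]), 1)

    records = []
    k = 0
    width = len(str(n))
    for i in range(n):
        common = dict(
            id=f"P{i + 1:0{width}d}",
            sex=str(sex[i]),
            age=float(age[i]),
            bmi=float(bmi[i]),
            dialysis_modality=str(modality[i]),
            waiting_time=float(waiting[i]),
            family_history_dm=bool(fh[i]),
            prior_transplants=int(retx[i]),
        )
        if known_mask[i]:
            records.append(PatientRecord(
                known_dm=str(dm_type[k]), hba1c=float(hba1c_known[k]),
                ogtt=None, **common))
            k += 1
        else:
            series = OGTTSeries(tuple(np.round(G_meas[i], 2)),
                                tuple(np.round(I_meas[i], 2)))
            records.append(PatientRecord(
                known_dm="none", hba1c=float(hba1c[i]), ogtt=series, **common))
    return CohortTable(tuple(records), provenance=provenance)


def null_params(seed: int = 0, n: int = 138) -> GeneratorParams:
    """Defaults with both structural covariate effects switched off."""
    return dataclasses.replace(GeneratorParams(), seed=seed, n=n,
                               sens_bmi_slope=0.0, secr_age_slope=0.0)


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Fixture:
    """A named cohort together with its expected-output snapshot."""

    name: str
    cohort: CohortTable
    expected: dict = field(default_factory=dict)


def _tiny_records() -> tuple[PatientRecord, ...]:
    """Six hand-written records spanning every classification branch."""
    return (
        PatientRecord("T1", "m", 63.0, 27.1, "HD", 5.2, True, 1, "type2",
                      7.2, ogtt=None),
        PatientRecord("T2", "f", 44.0, 24.0, "PD", 2.0, False, 0, "none", 5.6,
                      OGTTSeries((5.0, 8.6, 9.8, 10.6, 11.2),
                                 (7.0, 45.0, 60.0, 70.0, 80.0))),
        PatientRecord("T3", "m", 58.0, 29.5, "HD", 6.4, True, 0, "none", 5.5,
                      OGTTSeries((6.0, 9.0, 7.6, 7.2, 7.0),
                                 (9.0, 54.0, 40.0, 32.0, 28.0))),
        PatientRecord("T4", "f", 52.0, 26.0, "HD", 3.1, False, 0, "none", 5.8,
                      OGTTSeries((5.2, 8.2, 8.6, 8.5, 8.4),
                                 (8.0, 38.0, 52.0, 56.0, 58.0))),
        PatientRecord("T5", "m", 36.0, 22.5, "HD", 0.8, False, 1, "none", 5.9,
                      OGTTSeries((4.8, 7.4, 6.6, 6.0, 5.6),
                                 (6.0, 40.0, 30.0, 22.0, 18.0))),
        PatientRecord("T6", "f", 29.0, 21.0, "HD", 1.5, False, 0, "none", 5.2,
                      OGTTSeries((4.9, 8.0, 7.2, 6.2, 6.5),
                                 (8.0, 50.0, 40.0, 30.0, 25.0))),
    )


_TINY_EXPECTED_CLASSIFICATION = (
    ("T1", "known_dm", "", "DM"),
    ("T2", "new_dm", "", "DM"),
    ("T3", "prediabetes", "IFG", "iIFG"),
    ("T4", "prediabetes", "HBA1C_BAND;IGT", "iIGT"),
    ("T5", "prediabetes", "HBA1C_BAND", "NGT"),
    ("T6", "ngt", "", "NGT"),
)

#: Fig-1B-style criterion multiset used by the paper_like fixture:
#: 7 IFG, 20 IGT, 27 HbA1c-band assignments over 42 prediabetic patients,
#: 10 of whom hold more than one criterion.
PAPER_LIKE_CRITERIA = {"IFG": 7, "IGT": 20, "HBA1C_BAND": 27}
PAPER_LIKE_COUNTS = {"known_dm": 30, "new_dm": 4, "prediabetes": 42, "ngt": 62}
PAPER_LIKE_N_MULTI = 10

_POOL_SEED = 97
_POOL_N = 8000


def _template_prediabetic(slot: int, ifg: bool, igt: bool, band: bool
                          ) -> PatientRecord:
    """Deterministic synthetic record hitting an exact criterion subset."""
    glc0 = 6.0 if ifg else 4.8
    glc120 = 9.0 if igt else 6.2
    glc30 = glc0 + 3.4
    glc60 = glc0 + 2.2
    glc90 = (glc60 + glc120) / 2
    ins0 = 6.0
    series = OGTTSeries(
        (glc0, glc30, glc60, glc90, glc120),
        (ins0, ins0 + 18 * (glc30 - glc0), ins0 + 14 * (glc60 - glc0),
         ins0 + 10 * max(glc90 - glc0, 0.5), ins0 + 8 * max(glc120 - glc0, 0.5)),
    )
    return PatientRecord(
        id=f"S{slot:03d}", sex="m" if slot % 2 else "f",
        age=45.0 + (slot % 20), bmi=23.0 + (slot % 10) * 0.7,
        dialysis_modality="HD", waiting_time=2.0 + (slot % 7) * 0.5,
        family_history_dm=bool(slot % 3 == 0), prior_transplants=slot % 2,
        known_dm="none", hba1c=6.0 if band else 5.2, ogtt=series)


def _paper_like_cohort() -> CohortTable:
    """Seed-fixed n=138 cohort with category counts forced to (30, 4, 42, 62)
    and the prediabetes criterion multiset forced to the Fig-1B structure."""
    pool = generate_cohort(
        dataclasses.replace(GeneratorParams(), n=_POOL_N, seed=_POOL_SEED),
        provenance="paper_like pool")
    decomp = decompose_criterion_overlap(
        PAPER_LIKE_CRITERIA, PAPER_LIKE_COUNTS["prediabetes"], PAPER_LIKE_N_MULTI)

    buckets: dict[object, list[PatientRecord]] = {}
    for record in pool:
        status = classify_patient(record, DEFAULT_THRESHOLDS)
        if status.category == "prediabetes":
            key = ("pre", tuple(sorted(status.criteria)))
        else:
            key = (status.category,)
        buckets.setdefault(key, []).append(record)

    subset_of = {
        "IFG only": ("IFG",), "IGT only": ("IGT",), "HBA1C only": ("HBA1C_BAND",),
        "IFG+IGT": ("IFG", "IGT"), "IFG+HBA1C": ("HBA1C_BAND", "IFG"),
        "IGT+HBA1C": ("HBA1C_BAND", "IGT"),
        "IFG+IGT+HBA1C": ("HBA1C_BAND", "IFG", "IGT"),
    }
    chosen: list[PatientRecord] = []
    slot = 0
    for label, need in decomp.witness.items():
        subset = subset_of[label]
        have = buckets.get(("pre", subset), [])
        chosen.extend(have[:need])
        for _ in range(max(0, need - len(have))):  # deterministic fallback
            slot += 1
            chosen.append(_template_prediabetic(
                slot, "IFG" in subset, "IGT" in subset, "HBA1C_BAND" in subset))
    for category, need in (("known_dm", PAPER_LIKE_COUNTS["known_dm"]),
                           ("new_dm", PAPER_LIKE_COUNTS["new_dm"]),
                           ("ngt", PAPER_LIKE_COUNTS["ngt"])):
        have = buckets.get((category,), [])
        if len(have) < need:
            raise ParameterError(
                f"paper_like pool exhausted for {category}: {len(have)} < {need}")
        chosen.extend(have[:need])

    width = len(str(len(chosen)))
    records = tuple(dataclasses.replace(r, id=f"P{i + 1:0{width}d}")
                    for i, r in enumerate(chosen))
    return CohortTable(records, provenance="paper_like fixture")


def generate_fixture(name: str) -> Fixture:
    """Named deterministic fixtures: ``tiny``, ``paper_like`` or ``null``.

    * tiny — six hand-written records, one per classification branch, with
      the expected classification snapshot attached.
    * paper_like — n = 138 with category counts forced exactly to
      (30 known DM, 4 new DM, 42 prediabetes, 62 NGT) and the criterion
      multiset forced to (IFG 7, IGT 20, HbA1c 27; 10 multi-criterion).
    * null — generator defaults with both covariate effects removed.
    """
    if name == "tiny":
        cohort = CohortTable(_tiny_records(), provenance="tiny fixture")
        return Fixture(name, cohort, expected={
            "classification": _TINY_EXPECTED_CLASSIFICATION,
        })
    if name == "paper_like":
        return Fixture(name, _paper_like_cohort(), expected={
            "counts": dict(PAPER_LIKE_COUNTS),
            "display_percentages": {"any_disturbance": 55, "known_dm": 22,
                                    "new_dm": 3, "prediabetes": 30},
            "criterion_counts": dict(PAPER_LIKE_CRITERIA),
            "n_multi_criterion": PAPER_LIKE_N_MULTI,
        })
    if name == "null":
        return Fixture(name, generate_cohort(null_params(seed=11),
                                             provenance="null fixture"))
    raise ParameterError(f"unknown fixture {name!r}")
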