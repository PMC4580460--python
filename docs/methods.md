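# Methods

## Scope and data model

The package analyzes one tabular cohort of kidney-transplant waiting-list
candidates. Each record carries clinical covariates (sex, age, BMI,
dialysis modality, waiting time, family history of diabetes, prior
transplantations), HbA1c, the known-diabetes status, and — for patients
without known diabetes — an OGTT with glucose (mmol/l) and insulin
(µU/ml) on the fixed 0/30/60/90/120-min grid. Canonical units are mmol/l
and µU/ml; inputs may declare mg/dl (÷ 18.016) or pmol/l (÷ 6.0) in a
unit config. Units are declared, never inferred from magnitudes.

Missing data policy: a record with *no* OGTT measurements is valid only
for patients with known diabetes or a recorded fasting glucose
≥ 7 mmol/l (the clinical contraindication to a glucose challenge). A
record with a *partial* OGTT is kept but flagged and excluded from every
OGTT-derived computation with a logged reason; values are never imputed.
Writing a cohort emits only the retained fields, so partially measured
series are not round-tripped — by design, since they never enter any
computation.

## Indices

HOMA-IR uses the fasting pair directly, G₀·I₀/22.5. The Matsuda index is
evaluated with glucose converted to mg/dl and with plain arithmetic
means over all five sampled points (t = 0 included, no trapezoidal
weighting); this convention reproduces the magnitudes (~10–15) reported
for cohorts of this type, which are inconsistent with an mmol/l-scale
evaluation. The insulinogenic index uses the 0→30 min increments; a zero
glucose increment yields an absent value flagged `igi_undefined`, and a
non-positive ratio is *retained* but flagged `igi_negative` so that the
exclusion happens visibly downstream (log-scale models drop and count
those records) rather than silently at computation time. The disposition
index is the product of Matsuda ISI and IGI and is absent whenever
either factor is absent.

Scaling facts used as test invariants: the Matsuda index is homogeneous
of degree −1 in the insulin channel and in the glucose channel
separately, hence degree −2 under joint scaling of all measurements.

## Classification

Categories are assigned in a fixed decision order: known diabetes →
newly diagnosed diabetes (fasting ≥ 7.0 mmol/l, 2h ≥ 11.1 mmol/l or
HbA1c ≥ 6.5 %) → prediabetes by IFG (fasting 5.5–6.9 mmol/l), IGT
(2h 7.8–11.0 mmol/l) or HbA1c band (5.7–6.4 %) → normal glucose
tolerance. Band membership is implemented as `lower ≤ x < diabetes
cutoff`. At the 0.1-unit precision of reported measurements this is
identical to the closed printed bands (5.5 and 6.9 are IFG, 7.0 is
diabetic, etc.), but it keeps classification a total, severity-monotone
function on the continuum: a hypothetical 6.95 mmol/l does not fall into
a gap between "prediabetic" and "diabetic". The IFG lower bound is a
config constant (some guidelines use 5.6 mmol/l).

The glucose-tolerance subtype (NGT / iIFG / iIGT / IFG+IGT) is defined
by the two glucose criteria only; a patient prediabetic solely through
the HbA1c band sits in the NGT subtype bin while still counting as
prediabetes in prevalence summaries. This mirrors the common practice of
presenting fasting/2h-glucose state separately from the HbA1c pathway.
Patients with manifest diabetes never enter OGTT-dependent statistics
(indices, subtypes, ROC/relative risk).

Prevalence percentages are stored unrounded; report display uses
nearest-integer rounding with halves away from zero (76/138 → 55 %,
4/138 → 3 %). The criterion-overlap helper certifies whether a reported
multiset of criterion counts over a number of unique patients with a
stated multi-criterion count is combinatorially realizable (assuming
holders of two or three criteria), and returns a per-subset witness;
e.g. totals (7, 20, 27) over 42 patients with 10 multi-criterion holders
decompose uniquely into 8 double- and 2 triple-criterion patients.

## Adjusted models

"Factors independently affecting" an index are estimated with one joint
OLS per outcome. The outcome is natural-log transformed (all four
indices are right-skewed by construction) and z-scored; continuous
covariates are z-scored and binary covariates (sex, family history,
non-HD modality, re-transplantation) enter as 0/1, so the reported
slopes are standardized coefficients with |β| < 1 for non-degenerate
data. Two-sided t-based p-values and 95 % CIs come from the standard OLS
theory; no multiple-testing correction is applied. Rank-deficient
designs raise a collinearity error naming the offending columns. Group
contrasts across glucose-tolerance subtypes use the same transform with
subtype indicators plus sex/age/BMI adjustment and report the F-test on
the indicator block; empty subtype levels are dropped with a warning.

The regression machinery is statsmodels OLS; the test suite checks it
against an independent normal-equations implementation and calibrates
the type-I error of the age term at cohort size (nominal 5 %, accepted
3–7 % over 1,000 null replicates).

## Risk stratification

The empirical ROC evaluates every distinct predictor value with the
orientation "value ≥ threshold ⇒ predicted positive"; AUC is the
trapezoidal area, which equals Mann–Whitney concordance with ties
counted ½ (asserted exactly against brute-force enumeration). The
operating point maximizes Youden's J with ties broken toward the lowest
threshold — the conservative screening stance that flags more patients
at risk. Exposure is "predictor ≥ cutoff". If the optimal cutoff sits at
the extreme of the score range the 2×2 margin is empty and the relative
risk is returned flagged-undefined rather than as an error (this occurs
for uninformative predictors). Relative risk uses the Katz log-interval
with z = 1.96 and no continuity correction; a zero case cell flags the
result undefined. 2×2 tables can also be reconstructed from printed
sensitivity/specificity and group sizes (rounding half away from zero);
with 42/62 positives/negatives and (0.78, 0.55) this yields
(33, 28, 9, 34) and RR 2.5847 [1.38, 4.83], matching the published
age-cutoff result to display rounding and thereby validating both the
interval method and the reconstruction.

## Synthetic cohort generator

The generator is a structural test-bed, not a validated physiological
simulator: it exists so that the pipeline's qualitative claims
(prevalence mix, direction of covariate effects, index magnitudes) are
exercised end to end without patient-level data.

Covariates are drawn to match the study cohort's marginals: age from a
scaled Beta(2.6, 2.1) on [19, 76] (median ≈ 51), BMI from a clipped
log-normal (median 25.6, range [16.7, 38.2]), sex 80/138 male, modality
114/22/2 HD/PD/preemptive, family history 49/138, re-transplantation
29/138, waiting time from a clipped gamma (median ≈ 4 years). A
30/138 stratum receives known diabetes (14 type 1 / 16 type 2), no OGTT
and HbA1c from a shifted band, mirroring the study design.

Each remaining patient carries latent insulin sensitivity S and
secretory capacity B:

    ln S = s_bmi·(BMI − 25.6) + ε_S,           ε_S ~ N(0, 0.45)
    ln B = s_age·(age − 51) − γ·ln S + ε_B,    ε_B ~ N(0, 0.45)

with defaults s_bmi = −0.045 per kg/m², s_age = −0.013 per year and
compensation exponent γ = 0.5 — low sensitivity is partially offset by
hyperinsulinemic up-regulation of secretion, which deliberately weakens
the BMI→outcome association at the clinical-endpoint level. The OGTT
curve follows a discrete response model on the 30-min grid: fasting
glucose 4.9·S^−0.15 and fasting insulin 2.5·S^−0.8; a glucose load of
5.6 mmol/l appears as an excess pool that decays each step by
exp(−0.007·S·I); insulin responds linearly to the excess
(20·B µU/ml per mmol/l) with a first-phase weight profile
(1.0, 0.55, 0.35, 0.25) at 30/60/90/120 min. The early-spike profile is
what makes the printed magnitude pair (Matsuda ~10–15 *and* IGI ~20–31)
jointly attainable — a strictly proportional insulin response keeps late
insulin high and caps the Matsuda index below ~8. Multiplicative assay
noise (CV 4 %) applies to every measurement; HbA1c is affine in mean
OGTT glucose (3.34 + 0.30·Ḡ ± 0.18, clipped to [4.3, 8.6]).

Calibration constants were fixed in a single pass at n = 10,000 so that
ADA classification of generated patients yields a prediabetes share of
~30 % of all patients (realized 30.5–30.9 % across seeds) with a
realistic criterion mix, and index medians near the printed magnitudes
(Matsuda ≈ 9.9, IGI ≈ 20.5). The generated new-diabetes rate (~0.1 %) is
deliberately lower than the study's 3 %: those four patients are far-tail
2h-glucose outliers that the smooth latent model does not emulate, and
the forced fixture below supplies them instead.

What passing tests on these cohorts show — and what they do not: they
demonstrate that the pipeline recovers *directions* and calibrated error
rates under a known structural model (BMI→sensitivity −,
age→secretion −, compensation +) and that the arithmetic of
classification, prevalence and risk reconstruction is correct. They do
not validate the specific coefficient magnitudes, group means, AUCs or
the BMI-side relative risk of any real cohort, which depend on
patient-level data the generator does not claim to reproduce.

Fixtures: `tiny` is six hand-written records spanning every
classification branch with a committed expected snapshot; `paper_like`
is a deterministic n = 138 cohort whose category counts are forced
exactly to (30 known DM, 4 new DM, 42 prediabetes, 62 NGT) and whose
prediabetes criteria realize the multiset (IFG 7, IGT 20, HbA1c 27) with
10 multi-criterion patients (8 double + 2 triple), drawn from a large
seed-fixed pool by criterion subset with a deterministic template
fallback; `null` removes both structural slopes.

## Numerical and design choices

* Natural log for "log transformed"; indices are always transformed,
  covariates never.
* Youden J as the "optimum cut-off" criterion (standard in clinical ROC
  work); ties toward the lowest threshold.
* One joint model per outcome rather than separate per-factor adjusted
  models (matching a seven-factor coefficient table layout).
* The t = 0 point is included in the Matsuda means; no AUC-based
  variant.
* Exact closed-form checks (normal equations, pairwise concordance,
  literal index transcription) back every numerically delicate path at
  1e-12 relative tolerance.
* Problem sizes in the simulation-backed tests (n = 500 per replicate,
  100–200 replicates; 1,000 replicates at n = 138 for type-I
  calibration; n = 10,000 for generator calibration) were chosen as the
  smallest sizes at which the targeted effects are overwhelmingly
  resolvable, keeping the default suite fast.

## Known limitations

* The generator's insulin scale is anchored only on index magnitudes;
  absolute fasting insulin (and hence HOMA-IR ≈ 0.55 at the median) is
  lower than typical clinical values. No claim is made about absolute
  insulin levels.
* Classification assumes a single OGTT per patient; repeat-test
  confirmation logic is out of scope.
* The relative-risk interval is the plain Katz interval; no
  small-sample or zero-cell correction is offered.
* No plotting: the analysis scripts emit the tables underlying the
  usual figures, not the figures themselves.
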