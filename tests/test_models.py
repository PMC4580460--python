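"""Covariate-adjusted models: oracle equivalence, invariances, calibration."""

import dataclasses
import math

import numpy as np
import pytest

from ogttphen.cohort import CohortTable, OGTTSeries, PatientRecord
from ogttphen.errors import CollinearityError, DomainError
from ogttphen.models import fit_adjusted, group_contrast
from ogttphen.simulate import GeneratorParams, generate_cohort, null_params


def flat_series(glucose, insulin):
    """Constant OGTT: Matsuda ISI reduces to 10000/(18.016·g·i)."""
    return OGTTSeries((glucose,) * 5, (insulin,) * 5)


def make_record(pid, bmi=24.0, age=50.0, sex="f", waiting=2.0, fh=False,
                retx=0, series=None):
    series = series or OGTTSeries((4.9, 8.0, 7.2, 6.2, 6.5),
                                  (8, 50, 40, 30, 25))
    return PatientRecord(pid, sex, age, bmi, "HD", waiting, fh, retx, "none",
                         5.2, ogtt=series)


def cohort_with_loglinear_outcome(slope=0.3, n=8):
    """ln(Matsuda) is an exact affine function of BMI."""
    records = []
    for i in range(n):
        bmi = 20.0 + i
        insulin = 10000.0 / (18.016 * 5.0 * math.exp(1.0 + slope * bmi))
        records.append(make_record(f"L{i}", bmi=bmi,
                                   series=flat_series(5.0, insulin)))
    return CohortTable(tuple(records))


def normal_equations(X, y):
    """Independent closed-form OLS oracle: beta = (XᵀX)⁻¹Xᵀy, t-based p."""
    import scipy.stats
    n, p = X.shape
    beta = np.linalg.solve(X.T @ X, X.T @ y)
    resid = y - X @ beta
    sigma2 = resid @ resid / (n - p)
    cov = sigma2 * np.linalg.inv(X.T @ X)
    se = np.sqrt(np.diag(cov))
    t = beta / se
    pvals = 2 * scipy.stats.t.sf(np.abs(t), n - p)
    return beta, pvals


class TestFitAdjusted:
    def test_exact_loglinear_outcome_gives_unit_beta(self):
        fit = fit_adjusted(cohort_with_loglinear_outcome(), "matsuda_isi",
                           covariates=("bmi",))
        term = fit.term("bmi")
        assert term.beta == pytest.approx(1.0, abs=1e-9)
        assert term.p < 1e-10

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(8)
        records = []
        for i in range(12):
            bmi = float(rng.uniform(20, 32))
            age = float(rng.uniform(25, 72))
            insulin = float(rng.uniform(2, 30))
            records.append(make_record(f"O{i}", bmi=bmi, age=age,
                                       series=flat_series(5.0, insulin)))
        cohort = CohortTable(tuple(records))
        fit = fit_adjusted(cohort, "matsuda_isi", covariates=("age", "bmi"))

        y = np.log([10000.0 / (18.016 * 5.0 * r.ogtt.fpi) for r in records])
        y = (y - y.mean()) / y.std(ddof=1)
        def z(v):
            v = np.asarray(v, float)
            return (v - v.mean()) / v.std(ddof=1)
        X = np.column_stack([np.ones(12), z([r.age for r in records]),
                             z([r.bmi for r in records])])
        beta, pvals = normal_equations(X, y)
        assert fit.term("age").beta == pytest.approx(beta[1], rel=1e-9)
        assert fit.term("bmi").beta == pytest.approx(beta[2], rel=1e-9)
        assert fit.term("age").p == pytest.approx(pvals[1], rel=1e-6)
        assert fit.term("bmi").p == pytest.approx(pvals[2], rel=1e-6)

    def test_reorder_invariance(self, default_cohort):
        fit = fit_adjusted(default_cohort, "matsuda_isi")
        shuffled = CohortTable(tuple(reversed(default_cohort.records)))
        fit2 = fit_adjusted(shuffled, "matsuda_isi")
        for t1, t2 in zip(fit.terms, fit2.terms):
            assert t1.beta == pytest.approx(t2.beta, rel=1e-9)
            assert t1.p == pytest.approx(t2.p, rel=1e-9)

    def test_standardized_betas_invariant_to_covariate_units(self, default_cohort):
        months = CohortTable(tuple(
            dataclasses.replace(r, waiting_time=12.0 * r.waiting_time)
            for r in default_cohort.records))
        f_years = fit_adjusted(default_cohort, "igi")
        f_months = fit_adjusted(months, "igi")
        assert f_months.term("waiting_time").beta == pytest.approx(
            f_years.term("waiting_time").beta, rel=1e-9)

    def test_collinear_design_rejected_with_names(self):
        records = tuple(make_record(f"C{i}", bmi=20.0 + i, fh=bool(i % 2),
                                    retx=i % 2,
                                    series=flat_series(5.0, 5.0 + i))
                        for i in range(10))
        with pytest.raises(CollinearityError) as err:
            fit_adjusted(CohortTable(records), "matsuda_isi",
                         covariates=("bmi", "fh_dm", "prior_tx"))
        assert {"fh_dm", "prior_tx"} & set(err.value.columns)

    def test_too_few_records_rejected(self, tiny_cohort):
        with pytest.raises(DomainError):
            fit_adjusted(tiny_cohort, "matsuda_isi")

    def test_flagged_igi_records_excluded_and_counted(self):
        good = [make_record(f"G{i}", bmi=21.0 + i,
                            series=OGTTSeries((4.9, 8.0, 7.2, 6.2, 6.5),
                                              (8, 40 + 3 * i, 40, 30, 25)))
                for i in range(6)]
        bad = make_record("B1", series=OGTTSeries(
            (5.0, 7.5, 8.0, 8.0, 7.0), (20.0, 15.0, 30.0, 30.0, 25.0)))
        fit = fit_adjusted(CohortTable(tuple(good + [bad])), "igi",
                           covariates=("bmi",))
        assert fit.n_used == 6
        assert fit.n_excluded == 1


class TestParameterRecovery:
    def test_structural_signs_recovered_at_n800(self):
        """One large cohort recovers the four structural effect signs:
        BMI→sensitivity −, age→secretion −, BMI→secretion + (compensation),
        age and BMI → disposition −."""
        cohort = generate_cohort(
            dataclasses.replace(GeneratorParams(), n=800, seed=77))
        f_mats = fit_adjusted(cohort, "matsuda_isi")
        f_igi = fit_adjusted(cohort, "igi")
        f_disp = fit_adjusted(cohort, "disposition")
        assert f_mats.term("bmi").beta < 0 and f_mats.term("bmi").p < 0.05
        assert f_igi.term("age").beta < 0 and f_igi.term("age").p < 0.05
        assert f_igi.term("bmi").beta > 0 and f_igi.term("bmi").p < 0.05
        assert f_disp.term("age").beta < 0 and f_disp.term("age").p < 0.05
        assert f_disp.term("bmi").beta < 0

    def test_type_one_error_calibration_under_null(self):
        """Null generator, cohort-sized samples: the age term on log IGI
        rejects at the nominal 5 % rate (±2 %) over 1,000 replicates."""
        rejections = 0
        n_rep = 1000
        for rep in range(n_rep):
            cohort = generate_cohort(null_params(seed=20_000 + rep, n=138))
            fit = fit_adjusted(cohort, "igi", covariates=("sex", "age", "bmi"))
            rejections += fit.term("age").p < 0.05
        assert 0.03 <= rejections / n_rep <= 0.07


class TestGroupContrast:
    @staticmethod
    def _two_group_cohort(shift=1.0, n_per=12):
        records = []
        for i in range(n_per):
            igi_ngt = 12.0 + (i % 4)
            igi_ifg = igi_ngt * shift
            g_rise = 3.0
            for tag, fpg, igi in (("n", 4.8, igi_ngt), ("f", 6.0, igi_ifg)):
                ins0 = 6.0
                series = OGTTSeries(
                    (fpg, fpg + g_rise, fpg + 2.0, fpg + 1.5, fpg + 1.0),
                    (ins0, ins0 + igi * g_rise, 30.0, 25.0, 20.0))
                records.append(make_record(f"{tag}{i}", bmi=22.0 + (i % 5),
                                           age=40.0 + i,
                                           sex="m" if i % 2 else "f",
                                           series=series))
        return CohortTable(tuple(records))

    def test_identical_groups_give_null_f(self):
        with pytest.warns(UserWarning):
            p = group_contrast(self._two_group_cohort(shift=1.0), "igi")
        assert p > 0.99

    def test_large_shift_detected(self):
        with pytest.warns(UserWarning):
            p = group_contrast(self._two_group_cohort(shift=3.0, n_per=50),
                               "igi")
        assert p < 1e-3

    def test_single_group_rejected(self):
        records = tuple(make_record(f"S{i}", bmi=21.0 + i) for i in range(8))
        with pytest.raises(DomainError):
            group_contrast(CohortTable(records), "igi")

    def test_generator_cohort_contrast_runs(self, large_cohort):
        p = group_contrast(large_cohort, "disposition")
        assert 0 < p <= 1
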