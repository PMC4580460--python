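"""ADA classification, prevalence arithmetic and subtype grouping."""

import itertools

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ogttphen.classify import (GlycemicStatus, GlycemicThresholds,
                               classify_patient, decompose_criterion_overlap,
                               round_half_away, subtype_table,
                               summarize_prevalence)
from ogttphen.cohort import CohortTable, OGTTSeries, PatientRecord
from ogttphen.errors import DomainError, MissingDataError

SEVERITY = {"ngt": 0, "prediabetes": 1, "new_dm": 2}


def make_record(pid="X", fpg=4.9, g2h=6.5, hba1c=5.2, known_dm="none",
                with_ogtt=True):
    ogtt = None
    if with_ogtt:
        mid = max(fpg, g2h) + 1.0
        ogtt = OGTTSeries((fpg, mid, mid, (mid + g2h) / 2, g2h),
                          (8.0, 50.0, 40.0, 30.0, 25.0))
    return PatientRecord(pid, "f", 50.0, 24.0, "HD", 2.0, False, 0, known_dm,
                         hba1c, ogtt=ogtt,
                         fpg_screen=None if with_ogtt else fpg)


class TestClassifyPatient:
    @pytest.mark.parametrize("fpg,g2h,hba1c,category,criteria,subtype", [
        (4.9, 6.5, 5.2, "ngt", set(), "NGT"),
        (6.0, 7.0, 5.5, "prediabetes", {"IFG"}, "iIFG"),
        (5.0, 11.2, 5.6, "new_dm", set(), "DM"),
        (5.6, 8.0, 5.0, "prediabetes", {"IFG", "IGT"}, "IFG_IGT"),
        (4.8, 6.9, 5.9, "prediabetes", {"HBA1C_BAND"}, "NGT"),
    ])
    def test_examples(self, fpg, g2h, hba1c, category, criteria, subtype):
        status = classify_patient(make_record(fpg=fpg, g2h=g2h, hba1c=hba1c))
        assert status.category == category
        assert status.criteria == criteria
        assert status.subtype == subtype

    def test_known_dm_takes_precedence(self):
        status = classify_patient(make_record(known_dm="type1", with_ogtt=False,
                                              hba1c=7.5))
        assert status.category == "known_dm" and status.subtype == "DM"

    def test_fasting_screen_new_dm(self):
        status = classify_patient(make_record(fpg=7.4, with_ogtt=False))
        assert status.category == "new_dm"

    def test_missing_ogtt_without_exemption(self):
        record = PatientRecord("X", "f", 50, 24, "HD", 2, False, 0, "none",
                               5.2, ogtt=None, ogtt_partial=True)
        with pytest.raises(MissingDataError):
            classify_patient(record)

    @pytest.mark.parametrize("fpg,g2h,hba1c,category", [
        # closed boundaries as printed
        (5.5, 6.0, 5.0, "prediabetes"),
        (6.9, 6.0, 5.0, "prediabetes"),
        (7.0, 6.0, 5.0, "new_dm"),
        (5.0, 7.8, 5.0, "prediabetes"),
        (5.0, 11.0, 5.0, "prediabetes"),
        (5.0, 11.1, 5.0, "new_dm"),
        (5.0, 6.0, 5.7, "prediabetes"),
        (5.0, 6.0, 6.4, "prediabetes"),
        (5.0, 6.0, 6.5, "new_dm"),
        (5.4, 7.7, 5.6, "ngt"),
    ])
    def test_boundary_semantics(self, fpg, g2h, hba1c, category):
        status = classify_patient(make_record(fpg=fpg, g2h=g2h, hba1c=hba1c))
        assert status.category == category

    def test_invalid_status_combinations_rejected(self):
        with pytest.raises(ValueError):
            GlycemicStatus("prediabetes", frozenset(), "iIFG")
        with pytest.raises(ValueError):
            GlycemicStatus("ngt", frozenset({"IFG"}), "NGT")


# glucose values on the 0.1 mmol/l measurement grid, HbA1c on 0.1 %
fpg_values = st.integers(31, 90).map(lambda v: v / 10)
g2h_values = st.integers(40, 140).map(lambda v: v / 10)
hba1c_values = st.integers(43, 80).map(lambda v: v / 10)


class TestInvariants:
    @settings(max_examples=300, deadline=None, derandomize=True)
    @given(fpg=fpg_values, g2h=g2h_values, hba1c=hba1c_values,
           bump=st.sampled_from(["fpg", "g2h", "hba1c"]),
           delta=st.integers(1, 30).map(lambda v: v / 10))
    def test_threshold_monotone_severity(self, fpg, g2h, hba1c, bump, delta):
        """Raising any glycemic measurement never lowers the severity."""
        base = dict(fpg=fpg, g2h=g2h, hba1c=hba1c)
        bumped = dict(base)
        bumped[bump] = bumped[bump] + delta
        s0 = classify_patient(make_record(**base))
        s1 = classify_patient(make_record(**bumped))
        assert SEVERITY[s1.category] >= SEVERITY[s0.category]

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(fpg=fpg_values, g2h=g2h_values, hba1c=hba1c_values)
    def test_total_partition(self, fpg, g2h, hba1c):
        """Every valid record lands in exactly one category; non-DM records
        get exactly one of the four subtypes."""
        status = classify_patient(make_record(fpg=fpg, g2h=g2h, hba1c=hba1c))
        assert status.category in ("ngt", "prediabetes", "new_dm")
        if status.category != "new_dm":
            assert status.subtype in ("NGT", "iIFG", "iIGT", "IFG_IGT")
        else:
            assert status.subtype == "DM"


class TestPrevalence:
    def test_paper_like_mix(self, paper_like_cohort):
        summary = summarize_prevalence(paper_like_cohort)
        assert (summary.n_known_dm, summary.n_new_dm, summary.n_prediabetes,
                summary.n_ngt) == (30, 4, 42, 62)
        assert summary.display_percentages() == {
            "any_disturbance": 55, "known_dm": 22, "new_dm": 3,
            "prediabetes": 30}

    def test_counts_sum_to_total(self, default_cohort):
        s = summarize_prevalence(default_cohort)
        assert s.n_known_dm + s.n_new_dm + s.n_prediabetes + s.n_ngt == s.n_total
        assert sum(s.criterion_counts.values()) >= s.n_prediabetes
        assert s.pct_any_disturbance == pytest.approx(
            100 * (s.n_known_dm + s.n_new_dm + s.n_prediabetes) / s.n_total)

    def test_all_ngt_cohort(self):
        records = tuple(make_record(pid=f"N{i}") for i in range(5))
        s = summarize_prevalence(CohortTable(records))
        assert s.pct_any_disturbance == 0.0
        assert s.display_percentages()["any_disturbance"] == 0

    @pytest.mark.parametrize("x,expected", [
        (55.07, 55), (2.8985507, 3), (30.43, 30), (21.739, 22), (0.5, 1),
        (1.5, 2), (-0.5, -1),
    ])
    def test_display_rounding_half_away(self, x, expected):
        assert round_half_away(x) == expected


class TestOverlapDecomposition:
    def test_reported_multiset_is_feasible(self):
        d = decompose_criterion_overlap({"IFG": 7, "IGT": 20, "HBA1C_BAND": 27},
                                        n_patients=42, n_multi=10)
        assert d.excess == 12
        assert (d.n_double, d.n_triple) == (8, 2)
        assert sum(d.witness.values()) == 42
        # witness reproduces the per-criterion totals
        f = sum(v for k, v in d.witness.items() if "IFG" in k)
        g = sum(v for k, v in d.witness.items() if "IGT" in k)
        h = sum(v for k, v in d.witness.items() if "HBA1C" in k)
        assert (f, g, h) == (7, 20, 27)

    @pytest.mark.parametrize("counts,n,multi", [
        ({"IFG": 50, "IGT": 1, "HBA1C_BAND": 1}, 42, 10),   # single criterion > n
        ({"IFG": 7, "IGT": 20, "HBA1C_BAND": 27}, 42, 20),  # triples negative
        ({"IFG": 1, "IGT": 1, "HBA1C_BAND": 1}, 10, 0),     # counts < patients
    ])
    def test_infeasible_multisets_rejected(self, counts, n, multi):
        with pytest.raises(DomainError):
            decompose_criterion_overlap(counts, n, multi)


class TestSubtypeTable:
    def test_singleton_iifg(self):
        cohort = CohortTable((make_record(fpg=6.0),))
        assert subtype_table(cohort) == {"NGT": 0, "iIFG": 1, "iIGT": 0,
                                         "IFG_IGT": 0}

    def test_paper_like_partitions_non_dm(self, paper_like_cohort):
        counts = subtype_table(paper_like_cohort)
        assert sum(counts.values()) == 104  # 138 - 30 known - 4 new DM

    def test_hba1c_only_prediabetic_in_ngt_bin(self):
        cohort = CohortTable((make_record(hba1c=5.9),))
        assert subtype_table(cohort)["NGT"] == 1
        assert summarize_prevalence(cohort).n_prediabetes == 1

    def test_custom_thresholds_respected(self):
        stricter = GlycemicThresholds(ifg_lower=5.6)
        record = make_record(fpg=5.5)
        assert classify_patient(record).category == "prediabetes"
        assert classify_patient(record, stricter).category == "ngt"
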