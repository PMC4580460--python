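"""Glycemic classification and prevalence breakdown of both cohorts.

Writes results/classification_<cohort>.csv, results/prevalence.csv and
results/subtypes.csv and prints the headline percentages (share of the
waiting list with any disturbance in glucose metabolism, split into known
diabetes, newly diagnosed diabetes and prediabetes) plus the
glucose-tolerance subtype table of the non-diabetic patients.
"""

from pathlib import Path

import pandas as pd

from ogttphen import classify_cohort, read_cohort, subtype_table, \
    summarize_prevalence

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    prevalence_rows, subtype_rows = [], []
    for name in ("default", "paper_like"):
        cohort = read_cohort(RESULTS / f"cohort_{name}.csv")
        classify_cohort(cohort).to_csv(
            RESULTS / f"classification_{name}.csv", index=False)
        s = summarize_prevalence(cohort)
        pct = s.display_percentages()
        prevalence_rows.append({"cohort": name, "n": s.n_total,
                                "known_dm": s.n_known_dm, "new_dm": s.n_new_dm,
                                "prediabetes": s.n_prediabetes, "ngt": s.n_ngt,
                                **{f"pct_{k}": v for k, v in pct.items()}})
        counts = subtype_table(cohort)
        subtype_rows.append({"cohort": name, **counts})
        print(f"{name}: any disturbance {pct['any_disturbance']}% "
              f"(known DM {pct['known_dm']}%, new DM {pct['new_dm']}%, "
              f"prediabetes {pct['prediabetes']}%); "
              f"criteria {s.criterion_counts}, "
              f"{s.n_multi_criterion} patients with >1 criterion; "
              f"subtypes {counts}")
    pd.DataFrame(prevalence_rows).to_csv(RESULTS / "prevalence.csv", index=False)
    pd.DataFrame(subtype_rows).to_csv(RESULTS / "subtypes.csv", index=False)


if __name__ == "__main__":
    main()
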