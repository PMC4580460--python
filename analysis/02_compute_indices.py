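"""Compute the four OGTT indices for every patient of both cohorts.

Writes results/indices_<cohort>.csv and prints the index medians — the
headline magnitudes (Matsuda ISI ~10, insulinogenic index ~20) that the
generator calibration targets.
"""

from pathlib import Path

from ogttphen import compute_indices, read_cohort

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    for name in ("default", "paper_like"):
        cohort = read_cohort(RESULTS / f"cohort_{name}.csv")
        table = compute_indices(cohort)
        table.to_csv(RESULTS / f"indices_{name}.csv", index=False)
        with_ogtt = table.dropna(subset=["matsuda_isi"])
        med = with_ogtt[["homa_ir", "matsuda_isi", "igi", "disposition"]].median()
        print(f"{name}: {len(with_ogtt)}/{len(table)} patients with OGTT; "
              "medians "
              + ", ".join(f"{k}={v:.2f}" for k, v in med.items()))


if __name__ == "__main__":
    main()
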