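"""Apply the study's two exclusion rules (2.5 SD RT trimming per
participant x language x type cell; items missed by >40% of participants)
and write the cleaned table, the exclusion report, and the descriptive
condition summary.

Usage: python analysis/02_preprocess.py [--data results/trials.tsv] [--out results]
"""

import argparse
from pathlib import Path

from lexhdm import preprocess, synthetic


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--data", type=Path, default=Path("results/trials.tsv"))
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    trials = synthetic.read_trials(args.data)
    clean, report = preprocess.apply_exclusions(trials)
    synthetic.write_trials(clean, args.out / "trials_clean.tsv")
    report.write(args.out / "exclusions.txt")
    summary = preprocess.condition_summary(clean)
    summary.to_csv(args.out / "condition_summary.tsv", sep="\t", index=False,
                   float_format="%.6f")

    frac = 1 - report.n_trials_out / report.n_trials_in
    print(f"excluded {frac:.1%} of trials "
          f"({report.n_rt_outliers} RT outliers, {report.n_items_excluded} items)")
    print(f"max per-participant exclusion: "
          f"{max(report.per_participant_fraction.values()):.1%}")
    print(summary.to_string(index=False))


if __name__ == "__main__":
    main()
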