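"""Exclusions, RT filtering, ANOVAs and shift-aligned descriptives.

Applies the task exclusion criteria (chance-level accuracy, constant
confidence) and the log-RT outlier filter, then reports the group x level
mixed-design ANOVAs for accuracy and confidence and writes the peri-shift
(-5..+5 trials) accuracy and confidence tables.
"""

from pathlib import Path

import ruleshift as rs
from ruleshift import io
from ruleshift.pipeline import (
    apply_exclusions,
    rm_anova,
    rt_outlier_filter,
    shift_aligned_summary,
)

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    trials = io.read_trials(OUT / "trials.tsv")
    demo = io.read_demographics(OUT / "demographics.tsv")
    records = {
        pid: io.frame_to_records(sub)
        for pid, sub in trials.groupby("participant_id", sort=False)
    }
    cohort = rs.CohortDataset(trials, demo, None, records)

    cohort, report = apply_exclusions(cohort)
    io.write_table(report.participants, OUT / "exclusions.tsv")
    filtered, frac = rt_outlier_filter(cohort.trials)
    cohort.trials = filtered
    print(f"excluded {report.n_excluded} participants "
          f"(chance threshold {report.chance_threshold:.3f}); "
          f"RT outliers removed: {frac:.2%} of trials")

    for metric in ("outcome", "confidence"):
        tab = rm_anova(cohort, metric)
        print(f"\nmixed-design ANOVA on {metric} (group x level):")
        print(tab[["Source", "DF1", "DF2", "F", "p_unc"]].round(4).to_string(index=False))

    for metric in ("outcome", "confidence"):
        aligned = shift_aligned_summary(cohort, metric)
        io.write_table(aligned, OUT / f"shift_aligned_{metric}.tsv")
    print(f"\nshift-aligned tables written to {OUT}/")


if __name__ == "__main__":
    main()
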