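"""Trial-wise confidence models.

On the simulated cohort: (1) BIC selection of the post-shift recovery
functional form for accuracy and confidence; (2) the post-shift recovery
mixed models; (3) the previous-feedback model (confidence_t ~
accuracy_{t-1} x group) plus the post-correct/post-incorrect
confidence-change tests with Bonferroni correction; (4) the normative
models regressing confidence on the observer's General and Choice
Certainty with group interactions and VIF diagnostics.
"""

from pathlib import Path

import pandas as pd

import ruleshift as rs
from ruleshift import io
from ruleshift.pipeline import (
    apply_exclusions,
    feedback_change_tests,
    fit_feedback_model,
    fit_normative_model,
    fit_recovery_model,
    select_functional_form,
)

OUT = Path(__file__).resolve().parents[1] / "results"


def show(label, res, terms):
    print(f"\n{label}  [{res.formula}]")
    sub = res.coef[res.coef["term"].isin(terms)]
    print(sub.round(3).to_string(index=False))


def main() -> None:
    trials = io.read_trials(OUT / "trials.tsv")
    demo = io.read_demographics(OUT / "demographics.tsv")
    records = {
        pid: io.frame_to_records(sub)
        for pid, sub in trials.groupby("participant_id", sort=False)
    }
    cohort, _ = apply_exclusions(rs.CohortDataset(trials, demo, None, records))
    traces = pd.read_csv(OUT / "traces.tsv", sep="\t")
    traces = traces[traces["participant_id"].isin(demo["participant_id"])]

    results = []
    for outcome in ("outcome", "confidence"):
        form, table = select_functional_form(cohort, outcome)
        print(f"functional form for {outcome}: {form}")
        print(table.round(1).to_string(index=False))

    for st in ("ID", "ED"):
        res = fit_recovery_model(cohort, "confidence", st, form="linear")
        show(f"confidence recovery after {st} shifts", res, ["d1"])
        results.append(res)

    res = fit_feedback_model(cohort)
    show("feedback model", res, ["acc_lag", "group", "acc_lag:group"])
    results.append(res)

    print("\nconfidence-change tests (p* Bonferroni-corrected):")
    print(feedback_change_tests(cohort).round(3).to_string(index=False))

    joint = fit_normative_model(cohort, traces, spec="joint")
    show("normative model (joint)", joint,
         ["zgc", "zcc", "group", "zgc:group", "zcc:group"])
    print("VIF:")
    print(joint.vif.round(2).to_string(index=False))
    gc_only = fit_normative_model(cohort, traces, spec="gc_only")
    show("normative model (GC only)", gc_only, ["zgc", "group", "zgc:group"])
    results += [joint, gc_only]

    io.write_results(results, OUT / "models.json", seed=1)
    print(f"\nmodel results written to {OUT / 'models.json'}")


if __name__ == "__main__":
    main()
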