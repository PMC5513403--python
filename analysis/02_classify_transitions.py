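#!/usr/bin/env python
"""Assign 1A-1E risk subclasses and summarize transitions over follow-up.

Reads the validation cohort from results/, writes the per-patient class
table, the 5x5 transition matrix and the age-dependent class-boundary
curves used for plotting.
"""

import json
from pathlib import Path

import numpy as np

import adpkdval as av
from adpkdval.risk import boundary_table, classify_cohort

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    cohort = av.LongCohort.from_csv(RESULTS / "validation_cohort.csv")

    table = classify_cohort(cohort)
    table.to_csv(RESULTS / "risk_classes.csv", index=False, float_format="%.6f")
    print("baseline class counts:")
    print(table["class0"].value_counts().sort_index().to_string())

    summary = av.transition_summary(cohort)
    summary.to_frame().to_csv(RESULTS / "class_transitions.csv")
    print(
        f"\n{summary.n_assessed} patients assessed; "
        f"{summary.pct_progressed:.1f}% progressed to a more severe class, "
        f"{summary.pct_regressed:.1f}% regressed"
    )
    (RESULTS / "transition_summary.json").write_text(
        json.dumps(
            {
                "n_assessed": summary.n_assessed,
                "pct_progressed": summary.pct_progressed,
                "pct_regressed": summary.pct_regressed,
            },
            indent=2,
        )
        + "\n"
    )

    boundary_table(np.arange(19, 81)).to_csv(
        RESULTS / "class_boundaries.csv", index=False, float_format="%.3f"
    )
    print("wrote class-boundary curves for ages 19-80")


if __name__ == "__main__":
    main()
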