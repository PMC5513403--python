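#!/usr/bin/env python
"""Partially update the frozen model with additional kidney-volume data.

Model 1 adds each patient's second HtTKV measurement; Model 2 uses the
time-varying HtTKV at every visit.  Only the kidney-volume coefficient(s)
are refit — all other coefficients stay at their development values — and
performance is measured by patient-level five-fold cross-validation, with
and without the HtTKV x years interaction.  Appends the update rows to the
frozen-validation rows to produce the final report table.
"""

from pathlib import Path

import pandas as pd

import adpkdval as av

RESULTS = Path(__file__).resolve().parents[1] / "results"
CV_SEED = 77


def main() -> None:
    cohort = av.LongCohort.from_csv(RESULTS / "validation_cohort.csv")
    frozen = av.ModelCoefficients.from_json(
        RESULTS / f"development_coefficients_{av.MODE_CONTINUOUS}.json"
    )
    rows = []
    for row_name, (mode, with_int) in {
        "updated_model1": (av.UPDATE_MODEL1, False),
        "updated_model1_interaction": (av.UPDATE_MODEL1, True),
        "updated_model2": (av.UPDATE_MODEL2, False),
        "updated_model2_interaction": (av.UPDATE_MODEL2, True),
    }.items():
        report = av.cross_validated_report(
            cohort, frozen, mode, with_int, k=5, seed=CV_SEED, model_name=row_name
        )
        rows.append(report.to_row())
        print(
            f"{row_name}: R2 {report.r2:.3f}, bias {report.bias:.2f}, "
            f"P30 {report.p30:.1f}%, CRPS {report.crps:.2f} (n={report.n_obs})"
        )

    frozen_rows = pd.read_csv(RESULTS / "frozen_validation_reports.csv")
    update_rows = pd.DataFrame(rows)
    for col in ("aic", "crps"):  # None -> NaN so the columns stay numeric
        update_rows[col] = pd.to_numeric(update_rows[col])
    table = pd.concat([frozen_rows, update_rows], ignore_index=True)
    table.to_csv(RESULTS / "validation_reports.csv", index=False, float_format="%.6f")
    print(f"\nfull report table ({len(table)} rows) -> results/validation_reports.csv")


if __name__ == "__main__":
    main()
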