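#!/usr/bin/env python
"""Externally validate the frozen development models on the validation cohort.

Applies the development coefficients with every regression coefficient
held fixed, then computes the full agreement/discrimination suite (R2,
Bland-Altman bias and limits of agreement, correlation, P30, AIC and mean
Gaussian CRPS for the continuous model).  Writes one report row per model
and the Bland-Altman scatter data.
"""

from pathlib import Path

import pandas as pd

import adpkdval as av
from adpkdval.metrics import bland_altman_frame, validation_report
from adpkdval.model import marginal_loglik, terms_for_mode

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    cohort = av.LongCohort.from_csv(RESULTS / "validation_cohort.csv")
    rows = []
    for mode, row_name in [
        (av.MODE_RISK_CLASS, "validation_risk_class"),
        (av.MODE_CONTINUOUS, "validation_tkv"),
    ]:
        coeffs = av.ModelCoefficients.from_json(
            RESULTS / f"development_coefficients_{mode}.json"
        )
        preds = av.predict_cohort(coeffs, cohort)
        kwargs = {}
        if mode == av.MODE_CONTINUOUS:
            kwargs = dict(
                pred_sd=preds["pred_sd"],
                loglik=marginal_loglik(coeffs, cohort),
                n_params=len(terms_for_mode(mode)) + 2,
            )
        report = validation_report(row_name, preds["egfr_obs"], preds["egfr_pred"], **kwargs)
        rows.append(report.to_row())
        bland_altman_frame(preds["egfr_obs"], preds["egfr_pred"]).to_csv(
            RESULTS / f"bland_altman_{row_name}.csv", index=False, float_format="%.6f"
        )
        print(
            f"{row_name}: R2 {report.r2:.3f}, bias {report.bias:.2f}, "
            f"LoA ({report.loa_low:.1f}, {report.loa_high:.1f}), P30 {report.p30:.1f}%"
        )
    pd.DataFrame(rows).to_csv(
        RESULTS / "frozen_validation_reports.csv", index=False, float_format="%.6f"
    )


if __name__ == "__main__":
    main()
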