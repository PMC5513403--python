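#!/usr/bin/env python
"""Fit the Mayo-form linear mixed eGFR model on the development cohort.

Fits both versions — continuous log2 HtTKV and risk-subclass indicators —
by maximum likelihood and writes the coefficient sets to JSON.  These
frozen coefficients are what the validation step applies unchanged.
"""

from pathlib import Path

import adpkdval as av

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    cohort = av.LongCohort.from_csv(RESULTS / "development_cohort.csv")
    for mode in (av.MODE_CONTINUOUS, av.MODE_RISK_CLASS):
        coeffs = av.fit_development_model(cohort, mode)
        path = RESULTS / f"development_coefficients_{mode}.json"
        coeffs.to_json(path)
        print(f"{mode}: fit on {coeffs.n_obs} visits, loglik {coeffs.loglik:.1f}")
        print(f"  random-slope SD {coeffs.var_random_slope ** 0.5:.2f} /yr, "
              f"residual SD {coeffs.var_residual ** 0.5:.2f} ml/min/1.73m2")
        for term in ("intercept", "log2_httkv", "t", "t:log2_httkv"):
            if term in coeffs.beta:
                print(f"  beta[{term}] = {coeffs.beta[term]: .4f}")


if __name__ == "__main__":
    main()
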