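#!/usr/bin/env python
"""Simulate the development and validation cohorts used by every later step.

The validation cohort emulates a contemporary European ADPKD study sample
(median age ~34 y, eGFR ~82, HtTKV ~497 ml/m, second visit within 6-12
months then annual, follow-up 0.42-10.28 y, 3% of follow-up HtTKV missing
at random); the development cohort emulates the older, larger-kidney
population a kidney-volume prediction model is typically developed on.

Writes results/development_cohort.csv and results/validation_cohort.csv.
"""

from pathlib import Path

import adpkdval as av

RESULTS = Path(__file__).resolve().parents[1] / "results"
SEED = 20240901


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    dev_cfg = av.development_config(376, seed=SEED)
    val_cfg = av.GeneratorConfig(n_patients=214, seed=SEED + 1)
    for name, cfg in [("development", dev_cfg), ("validation", val_cfg)]:
        cohort = av.generate_cohort(cfg)
        cohort.to_csv(RESULTS / f"{name}_cohort.csv")
        cfg.to_json(RESULTS / f"{name}_generator_config.json")
        med = cohort.baselines[["age0", "egfr0", "httkv0"]].median()
        print(
            f"{name:12s} n={cohort.n_patients:4d} visits={cohort.n_visits:5d} "
            f"median age {med['age0']:.1f} y, eGFR0 {med['egfr0']:.1f}, "
            f"HtTKV0 {med['httkv0']:.0f} ml/m, "
            f"missing HtTKV {cohort.visits['httkv'].isna().mean() * 100:.1f}%"
        )


if __name__ == "__main__":
    main()
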