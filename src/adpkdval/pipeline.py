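"""End-to-end study replica: develop, freeze, validate, update, summarize.

``run_study`` wires the whole analysis together: simulate (or load) a
development and a validation cohort, fit the Mayo-form mixed model on the
development sample, apply it to the validation sample with every
coefficient frozen, partially update the kidney-volume coefficient with
additional HtTKV measurements (with and without time interactions,
cross-validated at the patient level), optionally multiply impute missing
HtTKV, and emit a single report table with one row per model in the
conventional order, plus Bland-Altman data, a class-transition summary and
a reproducibility manifest.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import GeneratorConfig, development_config, generate_cohort
from .data import LongCohort
from .imputation import impute_httkv, pool_reports
from .metrics import (
    R2_SSE,
    REPORT_COLUMNS,
    ValidationReport,
    bland_altman_frame,
    cross_validated_report,
    validation_report,
)
from .model import (
    MODE_CONTINUOUS,
    MODE_RISK_CLASS,
    UPDATE_MODEL1,
    UPDATE_MODEL2,
    ModelCoefficients,
    fit_development_model,
    marginal_loglik,
    predict_cohort,
    terms_for_mode,
)
from .risk import transition_summary

#: Report rows in their conventional (Table-style) order.
ROW_ORDER = [
    "validation_risk_class",
    "validation_tkv",
    "updated_model1",
    "updated_model1_interaction",
    "updated_model2",
    "updated_model2_interaction",
]

_UPDATE_SPECS = {
    "updated_model1": (UPDATE_MODEL1, False),
    "updated_model1_interaction": (UPDATE_MODEL1, True),
    "updated_model2": (UPDATE_MODEL2, False),
    "updated_model2_interaction": (UPDATE_MODEL2, True),
}


class PipelineError(RuntimeError):
    """A stage failure, wrapped with the stage name for context."""


@dataclass
class PipelineConfig:
    """Configuration of a full study run."""

    development: GeneratorConfig | str = field(default_factory=lambda: development_config(376))
    validation: GeneratorConfig | str = field(default_factory=lambda: GeneratorConfig(n_patients=214))
    model_modes: tuple[str, ...] = (MODE_RISK_CLASS, MODE_CONTINUOUS)
    updates: tuple[str, ...] = tuple(_UPDATE_SPECS)
    mi_enabled: bool = False
    mi_m: int = 30
    cv_k: int = 5
    master_seed: int = 0
    headline_r2: str = R2_SSE
    output_dir: str | None = None
    quiet: bool = True

    def __post_init__(self) -> None:
        if not self.model_modes:
            raise PipelineError("at least one model mode is required")
        unknown = [u for u in self.updates if u not in _UPDATE_SPECS]
        if unknown:
            raise PipelineError(f"unknown update rows {unknown}")
        if self.updates and self.cv_k < 2:
            raise PipelineError("cv_k must be at least 2 when updates are requested")


def _sub_seeds(master_seed: int, n: int) -> list[int]:
    # independent sub-seeds below 2^31, deterministic in the master seed
    state = np.random.SeedSequence(master_seed).generate_state(n, dtype=np.uint32)
    return [int(s % (2 ** 31)) for s in state]


def _resolve_cohort(source: GeneratorConfig | str, seed: int) -> LongCohort:
    if isinstance(source, GeneratorConfig):
        return generate_cohort(replace(source, seed=seed))
    return LongCohort.from_csv(source)


def run_study(config: PipelineConfig) -> dict:
    """Execute the full study and return (and optionally write) the bundle.

    The bundle holds the development coefficients, one ValidationReport per
    requested model row, Bland-Altman frames, the class-transition summary
    and a manifest of every derived seed.  A fixed master seed reproduces
    the bundle byte-for-byte.
    """
    seeds = _sub_seeds(config.master_seed, 4)
    seed_dev, seed_val, seed_cv, seed_mi = seeds
    manifest = {
        "master_seed": config.master_seed,
        "seed_development": seed_dev,
        "seed_validation": seed_val,
        "seed_cv": seed_cv,
        "seed_mi": seed_mi,
        "stages": [],
    }
    bundle: dict = {"manifest": manifest, "reports": {}, "bland_altman": {}}

    def _stage(name, fn):
        t0 = time.perf_counter()
        try:
            out = fn()
        except Exception as exc:
            manifest["stages"].append({"stage": name, "status": "failed", "error": str(exc)})
            raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        manifest["stages"].append({"stage": name, "status": "ok"})
        if not config.quiet:
            print(f"[{name}] done in {time.perf_counter() - t0:.2f}s")
        return out

    development = _stage("simulate_development", lambda: _resolve_cohort(config.development, seed_dev))
    validation = _stage("simulate_validation", lambda: _resolve_cohort(config.validation, seed_val))
    bundle["development_cohort"] = development
    bundle["validation_cohort"] = validation

    # class transitions on the validation sample
    bundle["transitions"] = _stage("transition_summary", lambda: transition_summary(validation))

    # development fits, one per requested mode
    coeffs: dict[str, ModelCoefficients] = {}
    for mode in config.model_modes:
        coeffs[mode] = _stage(f"fit_development_{mode}", lambda m=mode: fit_development_model(development, m))
    bundle["development_coefficients"] = coeffs

    # frozen-coefficient external validation
    # the continuous-mode validation needs complete HtTKV at baseline only,
    # so the frozen models are applied to every visit
    reports: dict[str, ValidationReport] = {}
    for mode in config.model_modes:
        row = "validation_tkv" if mode == MODE_CONTINUOUS else "validation_risk_class"

        def _validate(mode=mode, row=row):
            preds = predict_cohort(coeffs[mode], validation)
            kwargs = {}
            if mode == MODE_CONTINUOUS:
                # AIC/CRPS only for the continuous model, mirroring the
                # convention of leaving the risk-class row blank
                ll = marginal_loglik(coeffs[mode], validation)
                kwargs = {
                    "pred_sd": preds["pred_sd"],
                    "loglik": ll,
                    "n_params": len(terms_for_mode(mode)) + 2,
                }
            return validation_report(
                row, preds["egfr_obs"], preds["egfr_pred"],
                headline=config.headline_r2, **kwargs,
            ), preds

        reports[row], preds = _stage(f"validate_{row}", _validate)
        bundle["bland_altman"][row] = bland_altman_frame(preds["egfr_obs"], preds["egfr_pred"])

    # partial updates, cross-validated at the patient level
    if config.updates and MODE_CONTINUOUS in coeffs:
        base = coeffs[MODE_CONTINUOUS]

        def _update_row(row_name: str) -> ValidationReport:
            update_mode, with_int = _UPDATE_SPECS[row_name]

            def _one(cohort: LongCohort) -> ValidationReport:
                return cross_validated_report(
                    cohort, base, update_mode, with_int,
                    k=config.cv_k, seed=seed_cv, model_name=row_name,
                    headline=config.headline_r2,
                )

            if config.mi_enabled and validation.visits["httkv"].isna().any():
                imp = impute_httkv(validation, m=config.mi_m, seed=seed_mi)
                return pool_reports([_one(c) for c in imp.completed_cohorts])
            return _one(validation)

        for row_name in config.updates:
            reports[row_name] = _stage(f"update_{row_name}", lambda r=row_name: _update_row(r))

    bundle["reports"] = reports
    bundle["report_table"] = report_table(reports)

    if config.output_dir is not None:
        _stage("write_outputs", lambda: _write_bundle(bundle, coeffs, config))
    return bundle


def report_table(reports: dict[str, ValidationReport]) -> pd.DataFrame:
    rows = [reports[name].to_row() for name in ROW_ORDER if name in reports]
    return pd.DataFrame(rows, columns=REPORT_COLUMNS)


def _write_bundle(bundle: dict, coeffs: dict, config: PipelineConfig) -> None:
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    for mode, c in coeffs.items():
        c.to_json(out / f"development_coefficients_{mode}.json")
    bundle["report_table"].to_csv(out / "validation_reports.csv", index=False, float_format="%.6f")
    for name, frame in bundle["bland_altman"].items():
        frame.to_csv(out / f"bland_altman_{name}.csv", index=False, float_format="%.6f")
    trans = bundle["transitions"]
    trans.to_frame().to_csv(out / "class_transitions.csv")
    summary = {
        "n_assessed": trans.n_assessed,
        "pct_progressed": None if np.isnan(trans.pct_progressed) else trans.pct_progressed,
        "pct_regressed": None if np.isnan(trans.pct_regressed) else trans.pct_regressed,
    }
    (out / "transition_summary.json").write_text(json.dumps(summary, indent=2) + "\n")
    bundle["development_cohort"].to_csv(out / "development_cohort.csv")
    bundle["validation_cohort"].to_csv(out / "validation_cohort.csv")
    (out / "manifest.json").write_text(json.dumps(bundle["manifest"], indent=2) + "\n")
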