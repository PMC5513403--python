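"""Mayo-form linear mixed model for eGFR at t years of follow-up.

The model is

    eGFR_it = x_it' beta + b_i * t + eps_it,
    b_i ~ N(0, var_random_slope),   eps_it ~ N(0, var_residual),

where x_it contains the baseline predictors (log2 HtTKV or risk subclass,
age, sex, baseline eGFR), a linear term in years of follow-up t, and the
interaction of t with every baseline predictor.  The random effect is a
subject-specific slope on t (no random intercept by default).

Fitting goes through :class:`statsmodels.regression.mixed_linear_model.MixedLM`;
partial updating re-estimates only the kidney-volume coefficient(s) and the
variance components while every other coefficient is held frozen via an
offset, mirroring how an externally developed prediction model is
recalibrated on new data without discarding its published coefficients.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from statsmodels.regression.mixed_linear_model import MixedLM

from .data import LongCohort, PatientBaseline, sex_indicator
from .risk import assign_class, estimated_growth_rate, CLASS_LABELS

MODE_CONTINUOUS = "continuous_httkv"
MODE_RISK_CLASS = "risk_class"

_BASE_CONT = ["log2_httkv", "age0", "sex", "egfr0"]
_BASE_CLASS = ["class_1B", "class_1C", "class_1D", "class_1E", "age0", "sex", "egfr0"]

#: Fixed-effect term names, in design order, for each model mode.
CONTINUOUS_TERMS = ["intercept"] + _BASE_CONT + ["t"] + [f"t:{b}" for b in _BASE_CONT]
RISK_CLASS_TERMS = ["intercept"] + _BASE_CLASS + ["t"] + [f"t:{b}" for b in _BASE_CLASS]

#: Extra free term introduced by the two-measurement update (Model 1).
SECOND_TKV_TERM = "log2_httkv_second"

UPDATE_MODEL1 = "model1_two_tkv"
UPDATE_MODEL2 = "model2_time_varying"


class ModelError(ValueError):
    """Raised on contract violations in model construction or fitting."""


def terms_for_mode(mode: str) -> list[str]:
    if mode == MODE_CONTINUOUS:
        return list(CONTINUOUS_TERMS)
    if mode == MODE_RISK_CLASS:
        return list(RISK_CLASS_TERMS)
    raise ModelError(f"unknown model mode {mode!r}")


@dataclass
class ModelCoefficients:
    """Fixed effects plus variance components of the Mayo-form mixed model.

    ``beta`` maps term names to coefficients and must contain every term of
    the declared mode; updated models may carry the additional
    ``log2_httkv_second`` term.  Variances are in (ml/min/1.73m2)^2; the
    random-slope variance is per year of follow-up squared.
    """

    mode: str
    beta: dict[str, float]
    var_random_slope: float
    var_residual: float
    loglik: float | None = None
    n_obs: int | None = None
    update: str | None = None

    def __post_init__(self) -> None:
        required = terms_for_mode(self.mode)
        missing = [t for t in required if t not in self.beta]
        if missing:
            raise ModelError(f"coefficient map incomplete: missing {missing}")
        allowed = set(required) | {SECOND_TKV_TERM}
        extra = [t for t in self.beta if t not in allowed]
        if extra:
            raise ModelError(f"unexpected coefficient terms {extra}")
        if self.var_random_slope < 0 or self.var_residual < 0:
            raise ModelError("variance components must be non-negative")

    @property
    def terms(self) -> list[str]:
        base = terms_for_mode(self.mode)
        if SECOND_TKV_TERM in self.beta:
            base = base[:2] + [SECOND_TKV_TERM] + base[2:]
        return base

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "mode": self.mode,
            "beta": {k: float(v) for k, v in self.beta.items()},
            "var_random_slope": float(self.var_random_slope),
            "var_residual": float(self.var_residual),
            "loglik": None if self.loglik is None else float(self.loglik),
            "n_obs": self.n_obs,
            "update": self.update,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True) + "\n")

    @classmethod
    def from_dict(cls, d: Mapping) -> "ModelCoefficients":
        return cls(
            mode=d["mode"],
            beta=dict(d["beta"]),
            var_random_slope=d["var_random_slope"],
            var_residual=d["var_residual"],
            loglik=d.get("loglik"),
            n_obs=d.get("n_obs"),
            update=d.get("update"),
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "ModelCoefficients":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass(frozen=True)
class PredictionRecord:
    """A point prediction with its marginal predictive standard deviation."""

    patient_id: str
    t: float
    egfr_pred: float
    pred_sd: float


# ---------------------------------------------------------------------------
# design construction
# ---------------------------------------------------------------------------

def design_row(baseline: PatientBaseline | Mapping, t: float, mode: str) -> dict[str, float]:
    """Term-value map for one patient at follow-up time ``t``.

    In continuous mode the kidney-volume predictor is log2(HtTKV0); in
    risk-class mode it is four indicator terms for classes 1B-1E with 1A as
    the reference level.  Every ``t:`` interaction value is t times the
    corresponding baseline value, hence zero at t = 0.
    """
    if t < 0:
        raise ModelError("follow-up time t must be non-negative")
    if isinstance(baseline, PatientBaseline):
        b = {
            "httkv0": baseline.httkv0,
            "age0": baseline.age0,
            "sex": baseline.sex,
            "egfr0": baseline.egfr0,
        }
    else:
        b = dict(baseline)
    row: dict[str, float] = {"intercept": 1.0}
    if mode == MODE_CONTINUOUS:
        httkv0 = b.get("httkv0")
        if httkv0 is None or (isinstance(httkv0, float) and np.isnan(httkv0)):
            raise ModelError("httkv0 is required in continuous mode")
        row["log2_httkv"] = float(np.log2(httkv0))
    elif mode == MODE_RISK_CLASS:
        rate = estimated_growth_rate(b["httkv0"], b["age0"])
        label = assign_class(rate).label
        for cls in CLASS_LABELS[1:]:
            row[f"class_{cls}"] = 1.0 if label == cls else 0.0
    else:
        raise ModelError(f"unknown model mode {mode!r}")
    row["age0"] = float(b["age0"])
    row["sex"] = float(sex_indicator(b["sex"])) if isinstance(b["sex"], str) else float(b["sex"])
    row["egfr0"] = float(b["egfr0"])
    row["t"] = float(t)
    for name in list(row):
        if name not in ("intercept", "t"):
            row[f"t:{name}"] = float(t) * row[name]
    return row


def design_matrix(cohort: LongCohort, mode: str) -> pd.DataFrame:
    """Per-visit design in term order, plus patient_id / t_years / egfr_obs."""
    long = cohort.merged()
    out = pd.DataFrame(index=long.index)
    out["intercept"] = 1.0
    if mode == MODE_CONTINUOUS:
        if long["httkv0"].isna().any():
            raise ModelError("httkv0 is required in continuous mode")
        out["log2_httkv"] = np.log2(long["httkv0"].to_numpy(float))
    elif mode == MODE_RISK_CLASS:
        rates = estimated_growth_rate(
            long["httkv0"].to_numpy(float), long["age0"].to_numpy(float)
        )
        labels = np.array([assign_class(r).label for r in rates])
        for cls in CLASS_LABELS[1:]:
            out[f"class_{cls}"] = (labels == cls).astype(float)
    else:
        raise ModelError(f"unknown model mode {mode!r}")
    out["age0"] = long["age0"].to_numpy(float)
    out["sex"] = sex_indicator(long["sex"])
    out["egfr0"] = long["egfr0"].to_numpy(float)
    t = long["t_years"].to_numpy(float)
    out["t"] = t
    base_terms = _BASE_CONT if mode == MODE_CONTINUOUS else _BASE_CLASS
    for name in base_terms:
        out[f"t:{name}"] = t * out[name].to_numpy()
    out = out[terms_for_mode(mode)]
    out.insert(0, "patient_id", long["patient_id"].to_numpy())
    out["t_years"] = t
    out["egfr_obs"] = long["egfr_obs"].to_numpy(float)
    return out


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def _fit_mixedlm(
    endog: np.ndarray,
    exog: np.ndarray,
    groups: np.ndarray,
    t: np.ndarray,
    reml: bool = False,
    random_intercept: bool = False,
) -> "MixedLM":
    if exog.shape[0] <= exog.shape[1]:
        raise ModelError("not enough observations to fit the requested fixed effects")
    rank = np.linalg.matrix_rank(exog)
    if rank < exog.shape[1]:
        raise ModelError(
            "singular fixed-effect design (rank "
            f"{rank} < {exog.shape[1]}); check for a constant covariate such as a single sex"
        )
    exog_re = t[:, None] if not random_intercept else np.column_stack([np.ones_like(t), t])
    mod = MixedLM(endog, exog, groups=groups, exog_re=exog_re)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = mod.fit(reml=reml, maxiter=500)
    return res


def _variance_components(res, random_intercept: bool = False) -> tuple[float, float]:
    cov_re = np.asarray(res.cov_re)
    slope_idx = cov_re.shape[0] - 1
    return float(max(cov_re[slope_idx, slope_idx], 0.0)), float(res.scale)


def fit_development_model(
    cohort: LongCohort,
    mode: str = MODE_CONTINUOUS,
    reml: bool = False,
    random_intercept: bool = False,
) -> ModelCoefficients:
    """Fit the full Mayo-form mixed model to a (development) cohort.

    ML is the default so that AIC comparisons across fixed-effect
    structures are meaningful; pass ``reml=True`` for variance-component
    estimation free of fixed-effect degrees-of-freedom bias.
    """
    dm = design_matrix(cohort, mode)
    terms = terms_for_mode(mode)
    res = _fit_mixedlm(
        dm["egfr_obs"].to_numpy(),
        dm[terms].to_numpy(),
        dm["patient_id"].to_numpy(),
        dm["t_years"].to_numpy(),
        reml=reml,
        random_intercept=random_intercept,
    )
    beta = {term: float(res.fe_params[i]) for i, term in enumerate(terms)}
    v_slope, v_resid = _variance_components(res, random_intercept)
    return ModelCoefficients(
        mode=mode,
        beta=beta,
        var_random_slope=v_slope,
        var_residual=v_resid,
        loglik=float(res.llf),
        n_obs=int(len(dm)),
    )


# ---------------------------------------------------------------------------
# prediction
# ---------------------------------------------------------------------------

def predictive_sd(
    coeffs: ModelCoefficients, t: float | np.ndarray, conditional: bool = False
) -> float | np.ndarray:
    """Marginal predictive SD sqrt(t^2 * var_slope + var_resid).

    The marginal form integrates over the unobserved subject-specific slope
    and is the default for scoring new patients; ``conditional=True`` drops
    the random-slope contribution (residual noise only).
    """
    if conditional:
        return np.sqrt(coeffs.var_residual) * np.ones_like(np.asarray(t, dtype=float))
    return np.sqrt(np.asarray(t, dtype=float) ** 2 * coeffs.var_random_slope + coeffs.var_residual)


def predict_egfr(
    coeffs: ModelCoefficients, baseline: PatientBaseline | Mapping, t: float
) -> PredictionRecord:
    """Population-level prediction for one patient at time ``t``.

    The random effect enters at its zero mean; the predictive SD is the
    marginal sqrt(t^2 * var_random_slope + var_residual).
    """
    row = design_row(baseline, t, coeffs.mode)
    pred = sum(coeffs.beta[term] * row[term] for term in terms_for_mode(coeffs.mode))
    pid = baseline.patient_id if isinstance(baseline, PatientBaseline) else str(
        baseline.get("patient_id", "")
    )
    return PredictionRecord(
        patient_id=pid,
        t=float(t),
        egfr_pred=float(pred),
        pred_sd=float(predictive_sd(coeffs, t)),
    )


def predict_cohort(
    coeffs: ModelCoefficients, cohort: LongCohort, conditional_sd: bool = False
) -> pd.DataFrame:
    """Per-visit predictions from baseline covariates only.

    Returns a frame with patient_id, t_years, egfr_obs, egfr_pred, pred_sd.
    """
    dm = design_matrix(cohort, coeffs.mode)
    terms = terms_for_mode(coeffs.mode)
    betavec = np.array([coeffs.beta[t] for t in terms])
    pred = dm[terms].to_numpy() @ betavec
    out = dm[["patient_id", "t_years", "egfr_obs"]].copy()
    out["egfr_pred"] = pred
    out["pred_sd"] = predictive_sd(coeffs, dm["t_years"].to_numpy(), conditional_sd)
    return out


# ---------------------------------------------------------------------------
# partial updating
# ---------------------------------------------------------------------------

def update_design(
    cohort: LongCohort, update_mode: str, with_interaction: bool = False
) -> pd.DataFrame:
    """Per-visit design for the two updated models.

    Model 1 (``model1_two_tkv``) keeps the baseline log2 HtTKV term and adds
    a second log2 HtTKV from each patient's earliest follow-up visit with a
    non-missing measurement; patients without such a visit are excluded.
    Model 2 (``model2_time_varying``) substitutes the visit's concurrent
    measurement into the (refit) log2 HtTKV term; visits with missing HtTKV
    are excluded.  Frozen terms always keep their original baseline-based
    values — only the re-estimated terms see the new measurements, so the
    t x HtTKV interaction switches to the time-varying value only when it
    is itself refit.
    """
    dm = design_matrix(cohort, MODE_CONTINUOUS)
    long = cohort.merged()
    if update_mode == UPDATE_MODEL1:
        with_httkv = long.dropna(subset=["httkv"]).sort_values("t_years", kind="stable")
        second = with_httkv.groupby("patient_id", sort=False)["httkv"].first()
        if second.empty:
            raise ModelError(
                "model1_two_tkv requires at least one patient with a non-missing "
                "follow-up HtTKV measurement"
            )
        keep = long["patient_id"].isin(second.index).to_numpy()
        dm = dm.loc[keep].copy()
        dm[SECOND_TKV_TERM] = np.log2(
            second.reindex(long.loc[keep, "patient_id"]).to_numpy(float)
        )
    elif update_mode == UPDATE_MODEL2:
        keep = long["httkv"].notna().to_numpy()
        if not keep.any():
            raise ModelError("model2_time_varying requires non-missing visit HtTKV values")
        dm = dm.loc[keep].copy()
        log2_tv = np.log2(long.loc[keep, "httkv"].to_numpy(float))
        dm["log2_httkv"] = log2_tv
        if with_interaction:
            dm["t:log2_httkv"] = dm["t_years"].to_numpy() * log2_tv
    else:
        raise ModelError(f"unknown update mode {update_mode!r}")
    return dm.reset_index(drop=True)


def free_update_terms(update_mode: str, with_interaction: bool) -> list[str]:
    """Terms re-estimated by partial_update; everything else stays frozen."""
    if update_mode == UPDATE_MODEL1:
        free = ["log2_httkv", SECOND_TKV_TERM]
    elif update_mode == UPDATE_MODEL2:
        free = ["log2_httkv"]
    else:
        raise ModelError(f"unknown update mode {update_mode!r}")
    if with_interaction:
        free.append("t:log2_httkv")
    return free


def partial_update(
    coeffs: ModelCoefficients,
    cohort: LongCohort,
    update_mode: str,
    with_interaction: bool = False,
) -> ModelCoefficients:
    """Refit only the kidney-volume coefficient(s) on a new cohort.

    All other regression coefficients, including the intercept, are kept
    frozen at their original values via an offset; the variance components
    are always re-estimated.  The returned object carries the frozen
    coefficients bit-unchanged.
    """
    if coeffs.mode != MODE_CONTINUOUS:
        raise ModelError("partial updating is supported only in continuous_httkv mode")
    dm = update_design(cohort, update_mode, with_interaction)
    free = free_update_terms(update_mode, with_interaction)
    frozen = [t for t in terms_for_mode(MODE_CONTINUOUS) if t not in free]
    offset = dm[frozen].to_numpy() @ np.array([coeffs.beta[t] for t in frozen])
    res = _fit_mixedlm(
        dm["egfr_obs"].to_numpy() - offset,
        dm[free].to_numpy(),
        dm["patient_id"].to_numpy(),
        dm["t_years"].to_numpy(),
        reml=False,
    )
    beta = dict(coeffs.beta)
    for i, term in enumerate(free):
        beta[term] = float(res.fe_params[i])
    if update_mode == UPDATE_MODEL1 and SECOND_TKV_TERM not in free:  # pragma: no cover
        beta.setdefault(SECOND_TKV_TERM, 0.0)
    v_slope, v_resid = _variance_components(res)
    return ModelCoefficients(
        mode=MODE_CONTINUOUS,
        beta=beta,
        var_random_slope=v_slope,
        var_residual=v_resid,
        loglik=float(res.llf),
        n_obs=int(len(dm)),
        update=f"{update_mode}{'+interaction' if with_interaction else ''}",
    )


def predict_updated(
    coeffs: ModelCoefficients, cohort: LongCohort, update_mode: str | None = None
) -> pd.DataFrame:
    """Per-visit predictions from an updated model on its own design.

    ``update_mode`` (and whether the interaction was refit) defaults to
    what is recorded on the coefficients.
    """
    if update_mode is None:
        if coeffs.update is None:
            raise ModelError("coefficients carry no update mode; pass update_mode explicitly")
        update_mode = coeffs.update
    parts = update_mode.split("+")
    dm = update_design(cohort, parts[0], with_interaction="interaction" in parts)
    terms = [t for t in coeffs.terms if t in dm.columns]
    pred = dm[terms].to_numpy() @ np.array([coeffs.beta[t] for t in terms])
    out = dm[["patient_id", "t_years", "egfr_obs"]].copy()
    out["egfr_pred"] = pred
    out["pred_sd"] = predictive_sd(coeffs, dm["t_years"].to_numpy())
    return out


# ---------------------------------------------------------------------------
# likelihood evaluation of a frozen model on new data
# ---------------------------------------------------------------------------

def marginal_loglik(coeffs: ModelCoefficients, cohort: LongCohort) -> float:
    """Gaussian marginal log-likelihood of a cohort under fixed coefficients.

    Per patient the marginal covariance is var_slope * t t' + var_resid * I;
    used to attach an AIC to an externally developed model applied with all
    coefficients frozen.
    """
    dm = design_matrix(cohort, coeffs.mode)
    terms = terms_for_mode(coeffs.mode)
    resid = dm["egfr_obs"].to_numpy() - dm[terms].to_numpy() @ np.array(
        [coeffs.beta[t] for t in terms]
    )
    t_all = dm["t_years"].to_numpy()
    groups = dm["patient_id"].to_numpy()
    ll = 0.0
    for pid in pd.unique(groups):
        idx = groups == pid
        t = t_all[idx]
        r = resid[idx]
        cov = coeffs.var_random_slope * np.outer(t, t) + coeffs.var_residual * np.eye(len(t))
        sign, logdet = np.linalg.slogdet(cov)
        ll += -0.5 * (len(t) * np.log(2 * np.pi) + logdet + r @ np.linalg.solve(cov, r))
    return float(ll)
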