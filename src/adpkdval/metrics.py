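"""Agreement, accuracy and scoring metrics for eGFR predictions.

Implements the full performance suite of an external-validation report:
Bland-Altman bias and 95% limits of agreement, the P30 accuracy
percentage, two R-squared variants, AIC, and the continuous ranked
probability score (CRPS) for Gaussian predictive distributions, plus
patient-level k-fold cross-validation for the partially updated models.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import norm, pearsonr

from .data import LongCohort
from . import model as _model

R2_SSE = "one_minus_sse_sst"
R2_PEARSON = "squared_pearson"


class MetricError(ValueError):
    """Raised on invalid metric inputs."""


def _check_pair(obs, pred, min_len=2):
    obs = np.asarray(obs, dtype=float)
    pred = np.asarray(pred, dtype=float)
    if obs.shape != pred.shape:
        raise MetricError("observed and predicted vectors must have equal length")
    if obs.size < min_len:
        raise MetricError(f"need at least {min_len} observation/prediction pairs")
    return obs, pred


def bias_and_loa(obs, pred) -> tuple[float, float, float]:
    """Bland-Altman bias = mean(obs - pred) and 95% limits of agreement.

    Limits are bias +/- 1.96 * SD(obs - pred), SD with the n-1 denominator;
    1.96 is used literally rather than a t-quantile.
    """
    obs, pred = _check_pair(obs, pred)
    diff = obs - pred
    bias = float(diff.mean())
    sd = float(diff.std(ddof=1))
    return bias, bias - 1.96 * sd, bias + 1.96 * sd


def p30(obs, pred) -> float:
    """Percentage of predictions within 30% of the observed value (inclusive)."""
    obs, pred = _check_pair(obs, pred, min_len=1)
    if np.any(obs <= 0):
        raise MetricError("P30 requires positive observed values")
    within = np.abs(pred - obs) <= 0.30 * obs
    return 100.0 * float(within.mean())


def r_squared(obs, pred, variant: str = R2_SSE) -> float:
    """Explained variance, either 1 - SSE/SST or the squared Pearson correlation.

    The two coincide only when predictions are an unbiased linear fit of the
    observations, so validation reports carry both.
    """
    obs, pred = _check_pair(obs, pred)
    if np.ptp(obs) == 0:
        raise MetricError("R-squared undefined for constant observations")
    if variant == R2_SSE:
        sse = float(((obs - pred) ** 2).sum())
        sst = float(((obs - obs.mean()) ** 2).sum())
        return 1.0 - sse / sst
    if variant == R2_PEARSON:
        return float(pearsonr(obs, pred).statistic ** 2)
    raise MetricError(f"unknown R-squared variant {variant!r}")


def aic(loglik: float, n_params: int) -> float:
    """Akaike information criterion -2*loglik + 2*n_params."""
    if n_params < 1:
        raise MetricError("n_params must be at least 1")
    return -2.0 * float(loglik) + 2.0 * n_params


def crps_normal(mu, sigma, y):
    """CRPS of a Normal(mu, sigma) forecast against outcome y (closed form).

    sigma * [z(2*Phi(z) - 1) + 2*phi(z) - 1/sqrt(pi)] with z = (y-mu)/sigma;
    a degenerate sigma = 0 forecast scores |y - mu|.  Vectorized.
    """
    mu = np.asarray(mu, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.any(sigma < 0):
        raise MetricError("sigma must be non-negative")
    scalar = mu.ndim == sigma.ndim == y.ndim == 0
    mu, sigma, y = np.atleast_1d(*np.broadcast_arrays(mu, sigma, y))
    out = np.abs(y - mu).astype(float)
    pos = sigma > 0
    if np.any(pos):
        z = (y[pos] - mu[pos]) / sigma[pos]
        out[pos] = sigma[pos] * (
            z * (2.0 * norm.cdf(z) - 1.0) + 2.0 * norm.pdf(z) - 1.0 / np.sqrt(np.pi)
        )
    return float(out[0]) if scalar else out


def crps_sample(samples, y: float) -> float:
    """Empirical CRPS mean|X - y| - 0.5 * mean|X - X'| over all ordered pairs.

    The pairwise term is computed from the sorted sample in O(n log n),
    which makes million-draw Monte-Carlo cross-checks of the closed form
    practical.
    """
    x = np.sort(np.asarray(samples, dtype=float))
    n = x.size
    if n < 2:
        raise MetricError("need at least 2 samples")
    term1 = float(np.abs(x - y).mean())
    # sum_{i<j} (x_j - x_i) via sorted prefix weights; all n^2 ordered pairs
    weights = 2.0 * np.arange(1, n + 1) - n - 1.0
    mean_pair = 2.0 * float(weights @ x) / (n * n)
    return term1 - 0.5 * mean_pair


def mean_crps(predictions: pd.DataFrame, obs_col: str = "egfr_obs") -> float:
    """Average Gaussian CRPS over a prediction frame.

    Expects columns ``egfr_pred``, ``pred_sd`` and the observation column;
    every record must carry a predictive SD.
    """
    if "pred_sd" not in predictions.columns or predictions["pred_sd"].isna().any():
        raise MetricError(
            "mean_crps needs a predictive SD per record; use a model that "
            "provides one (mixed-model marginal SD)"
        )
    return float(
        np.mean(
            crps_normal(
                predictions["egfr_pred"].to_numpy(),
                predictions["pred_sd"].to_numpy(),
                predictions[obs_col].to_numpy(),
            )
        )
    )


# ---------------------------------------------------------------------------
# validation report (the Table-2 twin)
# ---------------------------------------------------------------------------

REPORT_COLUMNS = [
    "model",
    "n_obs",
    "r2",
    "r2_sse_sst",
    "r2_pearson",
    "bias",
    "loa_low",
    "loa_high",
    "correlation",
    "p30",
    "aic",
    "crps",
]


@dataclass
class ValidationReport:
    """One model's agreement/discrimination summary row.

    The headline ``r2`` is one of the two variants (configurable); both are
    always carried.  ``aic`` and ``crps`` are None where not applicable
    (e.g. the risk-class validation model is scored without a predictive
    distribution).
    """

    model: str
    n_obs: int
    r2: float
    r2_sse_sst: float
    r2_pearson: float
    bias: float
    loa_low: float
    loa_high: float
    correlation: float
    p30: float
    aic: float | None = None
    crps: float | None = None

    def to_row(self) -> dict:
        return {k: asdict(self)[k] for k in REPORT_COLUMNS}

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_row(), indent=2) + "\n")


def validation_report(
    model_name: str,
    obs,
    pred,
    pred_sd=None,
    loglik: float | None = None,
    n_params: int | None = None,
    headline: str = R2_SSE,
) -> ValidationReport:
    """Assemble the full metric row from observed/predicted vectors."""
    obs, pred = _check_pair(obs, pred)
    bias, lo, hi = bias_and_loa(obs, pred)
    r2_sse = r_squared(obs, pred, R2_SSE)
    r2_p = r_squared(obs, pred, R2_PEARSON)
    corr = float(pearsonr(obs, pred).statistic)
    crps = None
    if pred_sd is not None:
        crps = float(np.mean(crps_normal(pred, np.asarray(pred_sd, dtype=float), obs)))
    aic_val = None
    if loglik is not None and n_params is not None:
        aic_val = aic(loglik, n_params)
    return ValidationReport(
        model=model_name,
        n_obs=int(obs.size),
        r2=r2_sse if headline == R2_SSE else r2_p,
        r2_sse_sst=r2_sse,
        r2_pearson=r2_p,
        bias=bias,
        loa_low=lo,
        loa_high=hi,
        correlation=corr,
        p30=p30(obs, pred),
        aic=aic_val,
        crps=crps,
    )


def bland_altman_frame(obs, pred) -> pd.DataFrame:
    """Two-column data behind a Bland-Altman plot: pair mean vs difference."""
    obs, pred = _check_pair(obs, pred)
    return pd.DataFrame({"mean": (obs + pred) / 2.0, "diff": obs - pred})


# ---------------------------------------------------------------------------
# patient-level cross-validation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FoldAssignment:
    """Seeded patient-level partition into k folds of near-equal size."""

    k: int
    assignment: dict

    def fold_patients(self, fold: int) -> list:
        return [p for p, f in self.assignment.items() if f == fold]


def make_folds(cohort: LongCohort, k: int = 5, seed: int = 0) -> FoldAssignment:
    """Partition patients (all visits of a patient share a fold)."""
    if k < 2:
        raise MetricError("k must be at least 2")
    pids = cohort.patient_ids()
    if len(pids) < k:
        raise MetricError(f"need at least {k} patients for {k}-fold CV")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(pids))
    assignment = {pids[idx]: i % k for i, idx in enumerate(order)}
    return FoldAssignment(k=k, assignment=assignment)


def cross_validated_predictions(
    cohort: LongCohort,
    coeffs: "_model.ModelCoefficients",
    update_mode: str,
    with_interaction: bool = False,
    k: int = 5,
    seed: int = 0,
) -> pd.DataFrame:
    """Held-out predictions: partial_update on k-1 folds, predict the k-th."""
    folds = make_folds(cohort, k=k, seed=seed)
    parts = []
    for fold in range(k):
        test_pids = set(folds.fold_patients(fold))
        train = cohort.subset([p for p in cohort.patient_ids() if p not in test_pids])
        test = cohort.subset(test_pids)
        updated = _model.partial_update(coeffs, train, update_mode, with_interaction)
        parts.append(_model.predict_updated(updated, test))
    return pd.concat(parts, ignore_index=True)


def cross_validated_report(
    cohort: LongCohort,
    coeffs: "_model.ModelCoefficients",
    update_mode: str,
    with_interaction: bool = False,
    k: int = 5,
    seed: int = 0,
    model_name: str | None = None,
    headline: str = R2_SSE,
) -> ValidationReport:
    """Pooled metrics over all held-out predictions of a k-fold CV."""
    preds = cross_validated_predictions(cohort, coeffs, update_mode, with_interaction, k, seed)
    name = model_name or f"cv_{update_mode}{'+interaction' if with_interaction else ''}"
    return validation_report(
        name,
        preds["egfr_obs"],
        preds["egfr_pred"],
        pred_sd=preds["pred_sd"],
        headline=headline,
    )
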