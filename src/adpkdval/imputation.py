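"""Multiple imputation of missing HtTKV under a multivariate-normal model.

A data-augmentation (MCMC) sampler alternates between drawing the mean and
covariance of the joint imputation model from their conditional posterior
(normal-inverse-Wishart, Jeffreys prior) and drawing the missing values
from their conditional normal distribution given the observed variables.
HtTKV is imputed on the log2 scale — the prediction model uses log2 HtTKV
and joint normality is far more plausible there — and back-transformed, so
imputed volumes are always positive.

Only the follow-up HtTKV column may be missing; the imputation model joins
log2 HtTKV with visit time, baseline age, sex, the observed eGFR and the
baseline eGFR.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import invwishart

from .data import LongCohort, sex_indicator
from .metrics import ValidationReport

IMPUTATION_VARS = ["log2_httkv", "t_years", "age0", "sex", "egfr_obs", "egfr0"]


class ImputationError(ValueError):
    """Raised on unsupported missingness patterns or pooling inputs."""


@dataclass
class ImputationSet:
    """m completed copies of a cohort plus the sampler's provenance."""

    m: int
    completed_cohorts: list[LongCohort]
    seed: int
    n_burnin: int
    thin: int
    imputation_model_vars: list[str] = field(default_factory=lambda: list(IMPUTATION_VARS))

    def __post_init__(self) -> None:
        if self.m < 1 or len(self.completed_cohorts) != self.m:
            raise ImputationError("ImputationSet requires m >= 1 completed cohorts")

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for i, cohort in enumerate(self.completed_cohorts):
            cohort.to_csv(directory / f"imputation_{i:02d}.csv")
        manifest = {
            "m": self.m,
            "seed": self.seed,
            "n_burnin": self.n_burnin,
            "thin": self.thin,
            "imputation_model_vars": self.imputation_model_vars,
        }
        (directory / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")


def impute_httkv(
    cohort: LongCohort,
    m: int = 30,
    n_burnin: int = 500,
    thin: int = 100,
    seed: int = 0,
) -> ImputationSet:
    """Multiply impute missing follow-up HtTKV values.

    Draws m completed cohorts at thinned intervals of a single data-
    augmentation chain after burn-in.  A cohort with nothing missing
    returns m identical copies without running the sampler.
    """
    if m < 1:
        raise ImputationError("m must be at least 1")
    merged = cohort.merged()
    for col in ("egfr_obs", "age0", "egfr0", "httkv0"):
        if merged[col].isna().any():
            raise ImputationError(
                f"unsupported missingness pattern: column {col!r} has missing values; "
                "only follow-up HtTKV may be missing"
            )
    miss = merged["httkv"].isna().to_numpy()
    if not miss.any():
        return ImputationSet(
            m=m,
            completed_cohorts=[cohort.copy() for _ in range(m)],
            seed=seed,
            n_burnin=n_burnin,
            thin=thin,
        )

    z = np.column_stack(
        [
            np.log2(merged["httkv"].to_numpy(float)),
            merged["t_years"].to_numpy(float),
            merged["age0"].to_numpy(float),
            sex_indicator(merged["sex"]),
            merged["egfr_obs"].to_numpy(float),
            merged["egfr0"].to_numpy(float),
        ]
    )
    n, p = z.shape
    rng = np.random.default_rng(seed)
    # start the chain from the observed-HtTKV mean
    z[miss, 0] = np.nanmean(z[:, 0])

    completed: list[LongCohort] = []
    n_iter = n_burnin + (m - 1) * thin + 1
    for it in range(n_iter):
        # posterior draw of (mu, Sigma) given the current completed data
        zbar = z.mean(axis=0)
        resid = z - zbar
        s = resid.T @ resid
        sigma = invwishart.rvs(df=n - 1, scale=s, random_state=rng)
        mu = rng.multivariate_normal(zbar, sigma / n)
        # conditional draw of missing log2 HtTKV given the other variables
        s11 = sigma[1:, 1:]
        s01 = sigma[0, 1:]
        w = np.linalg.solve(s11, s01)
        cond_var = float(sigma[0, 0] - s01 @ w)
        cond_mean = mu[0] + (z[miss, 1:] - mu[1:]) @ w
        z[miss, 0] = cond_mean + rng.normal(0.0, np.sqrt(max(cond_var, 0.0)), miss.sum())
        if it >= n_burnin and (it - n_burnin) % thin == 0:
            filled = cohort.copy()
            imputed = np.power(2.0, z[miss, 0])
            col = filled.visits["httkv"].to_numpy(float)
            col[miss] = imputed
            filled.visits["httkv"] = col
            completed.append(filled)
    return ImputationSet(
        m=m, completed_cohorts=completed, seed=seed, n_burnin=n_burnin, thin=thin
    )


# ---------------------------------------------------------------------------
# pooling
# ---------------------------------------------------------------------------

def rubin_pool(estimates, variances=None) -> dict:
    """Rubin's rules for m scalar estimates (optionally with their variances).

    Returns the pooled mean, between-imputation variance B, within-
    imputation variance W (NaN when no variances supplied), and the total
    variance T = W + (1 + 1/m) B.
    """
    est = np.asarray(estimates, dtype=float)
    m = est.size
    if m < 2:
        raise ImputationError("Rubin pooling needs at least 2 imputations")
    qbar = float(est.mean())
    b = float(((est - qbar) ** 2).sum() / (m - 1))
    if variances is None:
        w = float("nan")
        t = float("nan")
    else:
        var = np.asarray(variances, dtype=float)
        if var.shape != est.shape:
            raise ImputationError("estimates and variances must have equal shape")
        w = float(var.mean())
        t = w + (1.0 + 1.0 / m) * b
    return {"estimate": qbar, "between": b, "within": w, "total": t, "m": m}


def pool_reports(reports: list[ValidationReport]) -> ValidationReport:
    """Pool m validation reports by the mean of every numeric field.

    Averaging preserves the limits-of-agreement identity because the limits
    are linear in the per-imputation bias and difference-SD.
    """
    if len(reports) < 2:
        raise ImputationError("pooling needs at least 2 reports")
    names = {r.model for r in reports}
    if len(names) != 1:
        raise ImputationError(f"cannot pool reports for different models: {sorted(names)}")
    if len({r.n_obs for r in reports}) != 1:
        raise ImputationError("cannot pool reports with differing n_obs")

    def _mean(attr):
        vals = [getattr(r, attr) for r in reports]
        if any(v is None for v in vals):
            return None
        return float(np.mean(vals))

    first = reports[0]
    return ValidationReport(
        model=first.model,
        n_obs=first.n_obs,
        r2=_mean("r2"),
        r2_sse_sst=_mean("r2_sse_sst"),
        r2_pearson=_mean("r2_pearson"),
        bias=_mean("bias"),
        loa_low=_mean("loa_low"),
        loa_high=_mean("loa_high"),
        correlation=_mean("correlation"),
        p30=_mean("p30"),
        aic=_mean("aic"),
        crps=_mean("crps"),
    )


def pool_coefficients(coefficient_sets, variance_sets=None) -> dict:
    """Rubin-pool a list of coefficient maps term by term.

    ``variance_sets`` (same shape, squared standard errors) enables the
    within/total variance components; without them only the pooled point
    estimate and between-imputation variance are defined.
    """
    if len(coefficient_sets) < 2:
        raise ImputationError("pooling needs at least 2 coefficient sets")
    terms = list(coefficient_sets[0])
    for cs in coefficient_sets[1:]:
        if list(cs) != terms:
            raise ImputationError("coefficient sets have mismatched terms")
    out = {}
    for term in terms:
        est = [cs[term] for cs in coefficient_sets]
        var = None if variance_sets is None else [vs[term] for vs in variance_sets]
        out[term] = rubin_pool(est, var)
    return out
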