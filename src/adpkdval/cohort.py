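"""Seeded synthetic ADPKD cohort generator.

Emulates the longitudinal structure of a prospective ADPKD cohort: adult
patients (age > 18, eGFR > 30 at enrolment) with baseline age / eGFR /
HtTKV centred on medians of 34 y, 82 ml/min/1.73m2 and 497 ml/m; a second
visit within 6-12 months of baseline and roughly annual visits thereafter;
exponential per-patient kidney growth spanning risk classes 1A-1E; linear
eGFR decline with subject-specific slopes; and a small MCAR missingness
rate in follow-up HtTKV.

All randomness flows from a single master seed through independent
deterministically derived sub-streams, so a config reproduces its cohort
byte-for-byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
import json

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .data import CohortError, LongCohort
from .model import MODE_CONTINUOUS, ModelCoefficients, design_matrix, terms_for_mode
from .risk import estimated_growth_rate

__all__ = [
    "GeneratorConfig",
    "default_truth",
    "generate_cohort",
    "ckd_epi_egfr",
    "inverse_ckd_epi_creatinine",
    "simulate_httkv_trajectory",
    "apply_missingness",
]


def default_truth() -> ModelCoefficients:
    """Generating fixed effects and variance components for the simulator.

    Chosen so that a median patient (log2 HtTKV ~ 9, age 34, eGFR0 82)
    declines by roughly 2 ml/min/1.73m2 per year, larger kidneys decline
    faster, and the t = 0 prediction sits near eGFR0.  Variance components
    give a between-patient slope SD of 2 and residual SD of 5
    ml/min/1.73m2, consistent with limits of agreement a few tens of
    ml/min/1.73m2 wide after five years of follow-up.
    """
    return ModelCoefficients(
        mode=MODE_CONTINUOUS,
        beta={
            "intercept": 34.0,
            "log2_httkv": -2.0,
            "age0": -0.25,
            "sex": 1.0,
            "egfr0": 0.9,
            "t": 8.0,
            "t:log2_httkv": -0.9,
            "t:age0": 0.01,
            "t:sex": 0.1,
            "t:egfr0": -0.03,
        },
        var_random_slope=4.0,
        var_residual=25.0,
    )


def development_config(n_patients: int = 376, seed: int = 0) -> "GeneratorConfig":
    """Config for a development cohort resembling the original model's sample.

    Older patients (median age ~44), larger kidneys (median HtTKV ~651
    ml/m), lower eGFR (median ~71) and longer follow-up than the default
    (validation-style) cohort.  The generating truth differs from the
    validation truth only in the kidney-volume terms — emulating the
    population and TKV-measurement-method differences that make an
    externally developed model slightly miscalibrated on new data, which is
    exactly what partial updating of the HtTKV coefficient is meant to
    correct.
    """
    truth = default_truth()
    truth.beta["log2_httkv"] = -2.2
    truth.beta["t:log2_httkv"] = -0.95
    return GeneratorConfig(
        n_patients=n_patients,
        seed=seed,
        age_target=(44.0, 10.0),
        age_range=(19.0, 70.0),
        egfr0_dist=(71.0, 25.0),
        baseline_httkv_dist=(651.0, 0.755),
        followup_range=(0.5, 11.0),
        max_followup=11.0,
        egfr_model_truth=truth,
    )


def noiseless_config(n_patients: int = 50, seed: int = 0) -> "GeneratorConfig":
    """All noise terms zero: observations equal the generating fixed effects.

    Used for closure checks — validating the generating model on such a
    cohort must give bias 0, P30 = 100 and R-squared 1 exactly.
    """
    truth = default_truth()
    truth.var_random_slope = 0.0
    truth.var_residual = 0.0
    return GeneratorConfig(
        n_patients=n_patients,
        seed=seed,
        egfr_model_truth=truth,
        slope_growth_coupling=0.0,
        httkv_noise_cv=0.0,
        egfr_noise_sd=0.0,
        missing_rate=0.0,
    )


@dataclass
class GeneratorConfig:
    """All knobs of the synthetic cohort generator, with study-like defaults."""

    n_patients: int = 214
    seed: int = 0
    age_range: tuple[float, float] = (19.0, 55.0)
    age_target: tuple[float, float] = (34.0, 9.6)  # accept/reject target mean, sd
    frac_female: float = 0.44
    height_dist: dict = field(
        default_factory=lambda: {"female": (1.65, 0.07), "male": (1.78, 0.07)}
    )
    baseline_httkv_dist: tuple[float, float] = (497.0, 0.65)  # median ml/m, log-sd
    egfr0_dist: tuple[float, float] = (82.0, 18.5)  # target median, sd (truncated > 30)
    growth_rate_dist: tuple[float, float] = (0.25, 0.002)  # lognormal sd, floor rate/yr
    growth_rate_bias: float = 2.3  # prospective growth vs the birth-anchored class rate
    slope_growth_coupling: float = -30.0  # ml/min/1.73m2/yr per unit growth-rate deviation
    egfr_model_truth: ModelCoefficients = field(default_factory=default_truth)
    visit_gap_first: tuple[float, float] = (0.5, 1.0)
    visit_jitter: float = 0.15
    followup_range: tuple[float, float] = (0.42, 10.28)
    max_followup: float = 10.28
    httkv_noise_cv: float = 0.05
    egfr_noise_sd: float = 5.0
    missing_rate: float = 0.03

    def __post_init__(self) -> None:
        if self.n_patients < 0:
            raise CohortError("n_patients must be non-negative")
        for name in ("frac_female", "missing_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise CohortError(f"{name} must lie in [0, 1], got {v}")
        if self.httkv_noise_cv < 0 or self.egfr_noise_sd < 0:
            raise CohortError("noise parameters must be non-negative")
        if self.max_followup < 0:
            raise CohortError("max_followup must be non-negative")
        if self.baseline_httkv_dist[0] <= 0 or self.baseline_httkv_dist[1] < 0:
            raise CohortError("baseline_httkv_dist requires positive median, non-negative spread")
        if self.egfr0_dist[0] <= 30:
            raise CohortError("egfr0 median must exceed the eligibility floor of 30")

    # flat key/value serialization (JSON); the truth model nests as its dict
    def to_json(self, path: str | Path) -> None:
        d = self.__dict__.copy()
        d["egfr_model_truth"] = self.egfr_model_truth.to_dict()
        Path(path).write_text(json.dumps(d, indent=2, sort_keys=True, default=list) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "GeneratorConfig":
        d = json.loads(Path(path).read_text())
        d["egfr_model_truth"] = ModelCoefficients.from_dict(d["egfr_model_truth"])
        for key in ("age_range", "age_target", "baseline_httkv_dist", "egfr0_dist",
                    "growth_rate_dist", "visit_gap_first", "followup_range"):
            if key in d:
                d[key] = tuple(d[key])
        if "height_dist" in d:
            d["height_dist"] = {k: tuple(v) for k, v in d["height_dist"].items()}
        return cls(**d)


# ---------------------------------------------------------------------------
# CKD-EPI (2009 creatinine equation; race coefficient omitted)
# ---------------------------------------------------------------------------

_KAPPA = {"female": 0.7, "male": 0.9}
_ALPHA = {"female": -0.329, "male": -0.411}


def ckd_epi_egfr(creatinine, age, sex: str):
    """CKD-EPI 2009 creatinine-based eGFR (ml/min/1.73m2).

    141 * min(Scr/k, 1)^a * max(Scr/k, 1)^-1.209 * 0.993^age * 1.018[female],
    with k = 0.7 / 0.9 and a = -0.329 / -0.411 for women / men.  The race
    coefficient is omitted.
    """
    creatinine = np.asarray(creatinine, dtype=float)
    age = np.asarray(age, dtype=float)
    if np.any(creatinine <= 0):
        raise CohortError("creatinine must be positive")
    if np.any(age < 0):
        raise CohortError("age must be non-negative")
    if sex not in _KAPPA:
        raise CohortError(f"sex must be 'female' or 'male', got {sex!r}")
    ratio = creatinine / _KAPPA[sex]
    out = (
        141.0
        * np.minimum(ratio, 1.0) ** _ALPHA[sex]
        * np.maximum(ratio, 1.0) ** -1.209
        * 0.993 ** age
    )
    if sex == "female":
        out = out * 1.018
    return float(out) if out.ndim == 0 else out


def inverse_ckd_epi_creatinine(egfr: float, age: float, sex: str) -> float:
    """Serum creatinine (mg/dL) whose CKD-EPI eGFR equals ``egfr``.

    Synthetic-data convenience only: the generator parameterizes eGFR
    directly and back-derives a consistent creatinine.  eGFR is strictly
    decreasing in creatinine, so the root is unique.
    """
    if egfr <= 0:
        raise CohortError("egfr must be positive")
    f = lambda scr: ckd_epi_egfr(scr, age, sex) - egfr
    lo, hi = 1e-3, 50.0
    if f(lo) < 0 or f(hi) > 0:
        raise CohortError(f"eGFR {egfr} outside invertible range at age {age}")
    return float(brentq(f, lo, hi, xtol=1e-10))


# ---------------------------------------------------------------------------
# trajectory primitives
# ---------------------------------------------------------------------------

def simulate_httkv_trajectory(
    httkv0: float,
    rate: float,
    times,
    noise_cv: float = 0.0,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Exponential HtTKV growth httkv0*(1+rate)^t with multiplicative noise.

    The lognormal noise is mean-corrected so the expectation at every time
    equals the deterministic curve; ``noise_cv = 0`` returns the curve
    exactly.
    """
    times = np.asarray(times, dtype=float)
    if np.any(times < 0):
        raise CohortError("times must be non-negative")
    if httkv0 <= 0:
        raise CohortError("httkv0 must be positive")
    if rate <= -1:
        raise CohortError("growth rate must exceed -1")
    curve = httkv0 * (1.0 + rate) ** times
    if noise_cv == 0:
        return curve
    rng = np.random.default_rng(rng)
    sigma = np.sqrt(np.log1p(noise_cv ** 2))
    noise = rng.lognormal(mean=-0.5 * sigma ** 2, sigma=sigma, size=times.shape)
    return curve * noise


def apply_missingness(
    cohort: LongCohort, rate: float, rng: np.random.Generator | int | None = None
) -> LongCohort:
    """Set each follow-up HtTKV missing independently with probability ``rate``.

    Baseline httkv0 is never removed (a baseline measurement is an
    eligibility requirement of the classification).
    """
    if not 0 <= rate <= 1:
        raise CohortError("missing rate must lie in [0, 1]")
    out = cohort.copy()
    if rate == 0 or len(out.visits) == 0:
        return out
    rng = np.random.default_rng(rng)
    mask = rng.random(len(out.visits)) < rate
    out.visits.loc[mask, "httkv"] = np.nan
    return out


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

def _truncated_normal(rng, mean, sd, lo, hi, size):
    """Resampling-based truncated normal (exact, simple, fast enough here)."""
    out = np.empty(size)
    todo = np.arange(size)
    while todo.size:
        draw = rng.normal(mean, sd, size=todo.size)
        ok = (draw > lo) & (draw < hi)
        out[todo[ok]] = draw[ok]
        todo = todo[~ok]
    return out


def _visit_times(rng, gap_first, jitter, followup) -> np.ndarray:
    t1 = rng.uniform(*gap_first)
    if t1 > followup:
        return np.array([followup])
    times = [t1]
    t = t1
    while True:
        t = t + 1.0 + rng.uniform(-jitter, jitter)
        if t > followup:
            break
        times.append(t)
    return np.asarray(times)


def generate_cohort(config: GeneratorConfig) -> LongCohort:
    """Draw a complete synthetic longitudinal cohort from the config.

    Baselines are drawn first (sex, age, height, eGFR0, HtTKV0, a hidden
    per-patient growth rate), then per-patient visit schedules, then HtTKV
    and eGFR observations; finally MCAR missingness is punched into the
    follow-up HtTKV column.  Identical configs give identical cohorts.
    """
    n = config.n_patients
    if n == 0:
        return LongCohort.empty()
    streams = np.random.SeedSequence(config.seed).spawn(6)
    rng_base, rng_sched, rng_httkv, rng_egfr, rng_miss, rng_rate = (
        np.random.default_rng(s) for s in streams
    )

    sex = np.where(rng_base.random(n) < config.frac_female, "female", "male")
    age0 = _truncated_normal(
        rng_base, config.age_target[0], config.age_target[1],
        config.age_range[0], config.age_range[1], n,
    )
    height = np.array(
        [rng_base.normal(*config.height_dist[s]) for s in sex]
    ).clip(1.4, 2.1)
    med, logsd = config.baseline_httkv_dist
    httkv0 = np.exp(rng_base.normal(np.log(med), logsd, size=n)).clip(min=60.0)
    egfr0 = _truncated_normal(
        rng_base, config.egfr0_dist[0], config.egfr0_dist[1], 30.0, 180.0, n
    )
    creatinine0 = np.array(
        [inverse_ckd_epi_creatinine(e, a, s) for e, a, s in zip(egfr0, age0, sex)]
    )

    # hidden forward growth rate: lognormal scatter around the class-typical
    # rate implied by the baseline age/HtTKV pair
    rate_sd, rate_floor = config.growth_rate_dist
    # prospective adult growth runs well above the lifetime-average rate the
    # birth-anchored classification implies, which is what drives patients
    # into more severe classes over follow-up
    base_rate = config.growth_rate_bias * np.maximum(
        estimated_growth_rate(httkv0, age0), rate_floor
    )
    if rate_sd > 0:
        true_rate = base_rate * rng_rate.lognormal(
            mean=-0.5 * rate_sd ** 2, sigma=rate_sd, size=n
        )
    else:
        true_rate = base_rate.copy()
    true_rate = np.maximum(true_rate, rate_floor)

    pid = np.array([f"P{i:05d}" for i in range(n)])
    baselines = pd.DataFrame(
        {
            "patient_id": pid,
            "sex": sex,
            "age0": age0,
            "height_m": height,
            "creatinine0": creatinine0,
            "egfr0": egfr0,
            "httkv0": httkv0,
            "true_growth_rate": true_rate,
        }
    )

    # visit schedules
    vis_pid, vis_t = [], []
    followups = rng_sched.uniform(*config.followup_range, size=n).clip(
        max=config.max_followup
    )
    for i in range(n):
        times = _visit_times(
            rng_sched, config.visit_gap_first, config.visit_jitter, followups[i]
        )
        vis_pid.extend([pid[i]] * len(times))
        vis_t.extend(times)
    visits = pd.DataFrame({"patient_id": vis_pid, "t_years": np.asarray(vis_t)})

    # follow-up HtTKV along each patient's exponential curve
    httkv_obs = np.empty(len(visits))
    pos = 0
    for i in range(n):
        k = int((visits["patient_id"] == pid[i]).sum())
        tvals = visits["t_years"].to_numpy()[pos : pos + k]
        httkv_obs[pos : pos + k] = simulate_httkv_trajectory(
            httkv0[i], true_rate[i], tvals, config.httkv_noise_cv, rng_httkv
        )
        pos += k
    visits["httkv"] = httkv_obs

    # eGFR from the generating mixed model: fixed effects + random slope
    # (optionally coupled to the hidden growth rate) + residual noise
    truth = config.egfr_model_truth
    visits["egfr_obs"] = 1.0  # placeholder so design_matrix can run
    cohort = LongCohort(baselines, visits)
    dm = design_matrix(cohort, truth.mode)
    terms = terms_for_mode(truth.mode)
    fixed = dm[terms].to_numpy() @ np.array([truth.beta[t] for t in terms])
    slope_sd = np.sqrt(truth.var_random_slope)
    b = rng_egfr.normal(0.0, slope_sd, size=n) if slope_sd > 0 else np.zeros(n)
    if config.slope_growth_coupling != 0.0:
        b = b + config.slope_growth_coupling * (true_rate - np.median(true_rate))
    b_per_visit = pd.Series(b, index=pid).reindex(visits["patient_id"]).to_numpy()
    eps = (
        rng_egfr.normal(0.0, config.egfr_noise_sd, size=len(visits))
        if config.egfr_noise_sd > 0
        else np.zeros(len(visits))
    )
    egfr = fixed + b_per_visit * visits["t_years"].to_numpy() + eps
    cohort.visits["egfr_obs"] = np.maximum(egfr, 1.0)

    return apply_missingness(cohort, config.missing_rate, rng_miss)
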