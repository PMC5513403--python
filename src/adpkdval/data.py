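"""Core data containers for longitudinal ADPKD cohorts.

A cohort is stored in two aligned tables: one row per patient holding the
baseline (t = 0) covariates, and one row per follow-up visit holding the
time since baseline, the observed eGFR and the (possibly missing)
height-adjusted total kidney volume (HtTKV).  The on-disk interchange
format is a single long-format CSV with the baseline columns repeated on
every visit row.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

#: Fixed header of the long-format cohort CSV.  Missing HtTKV is an empty field.
COHORT_COLUMNS = [
    "patient_id",
    "sex",
    "age0",
    "height_m",
    "creatinine0",
    "egfr0",
    "httkv0",
    "t_years",
    "egfr_obs",
    "httkv",
]

BASELINE_COLUMNS = ["patient_id", "sex", "age0", "height_m", "creatinine0", "egfr0", "httkv0"]
VISIT_COLUMNS = ["patient_id", "t_years", "egfr_obs", "httkv"]

SEXES = ("female", "male")


class CohortError(ValueError):
    """Raised when a cohort violates its structural contract."""


@dataclass(frozen=True)
class PatientBaseline:
    """One patient's time-zero covariates.

    ``true_growth_rate`` is populated only by the synthetic generator (the
    per-patient yearly fractional kidney growth used as simulation truth);
    it is never written to the interchange CSV and is hidden from every
    analysis stage.
    """

    patient_id: str
    sex: str
    age0: float
    height: float
    egfr0: float
    httkv0: float
    creatinine0: float | None = None
    true_growth_rate: float | None = None

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise CohortError(f"sex must be one of {SEXES}, got {self.sex!r}")
        if not self.age0 > 18:
            raise CohortError(f"age0 must exceed 18 y (eligibility), got {self.age0}")
        if not self.egfr0 > 30:
            raise CohortError(f"egfr0 must exceed 30 ml/min/1.73m2 (eligibility), got {self.egfr0}")
        if not self.height > 0:
            raise CohortError("height must be positive")
        if not self.httkv0 > 0:
            raise CohortError("httkv0 must be positive")


@dataclass(frozen=True)
class VisitRecord:
    """One follow-up observation: time since baseline, eGFR, optional HtTKV."""

    patient_id: str
    t: float
    egfr_obs: float
    httkv: float | None = None

    def __post_init__(self) -> None:
        if self.t < 0:
            raise CohortError("visit time must be non-negative")
        if not self.egfr_obs > 0:
            raise CohortError("observed eGFR must be positive")
        if self.httkv is not None and not np.isnan(self.httkv) and self.httkv <= 0:
            raise CohortError("HtTKV must be positive when present")


@dataclass
class LongCohort:
    """Baseline table plus visit table, with the structural invariants enforced.

    ``baselines`` has one row per patient (columns ``BASELINE_COLUMNS`` and,
    for synthetic cohorts, ``true_growth_rate``); ``visits`` has one row per
    follow-up visit (columns ``VISIT_COLUMNS``) with NaN marking missing HtTKV.
    """

    baselines: pd.DataFrame
    visits: pd.DataFrame

    def __post_init__(self) -> None:
        self.baselines = self.baselines.reset_index(drop=True)
        self.visits = self.visits.reset_index(drop=True)
        self.validate()

    # -- contract ---------------------------------------------------------
    def validate(self) -> None:
        for col in BASELINE_COLUMNS:
            if col not in self.baselines.columns:
                raise CohortError(f"baseline table missing column {col!r}")
        for col in VISIT_COLUMNS:
            if col not in self.visits.columns:
                raise CohortError(f"visit table missing column {col!r}")
        if self.baselines["patient_id"].duplicated().any():
            raise CohortError("duplicate patient_id in baseline table")
        if self.n_patients == 0:
            if len(self.visits):
                raise CohortError("visits present but no baselines")
            return
        known = set(self.baselines["patient_id"])
        orphans = set(self.visits["patient_id"]) - known
        if orphans:
            raise CohortError(f"visits reference unknown patients: {sorted(orphans)[:5]}")
        without_visit = known - set(self.visits["patient_id"])
        if without_visit:
            raise CohortError(
                f"{len(without_visit)} patients have no follow-up visit "
                f"(e.g. {sorted(without_visit)[:3]})"
            )
        if not self.baselines["age0"].gt(18).all():
            raise CohortError("eligibility violated: age0 must exceed 18 y")
        if not self.baselines["egfr0"].gt(30).all():
            raise CohortError("eligibility violated: egfr0 must exceed 30")
        if (self.visits["t_years"] < 0).any():
            raise CohortError("negative visit times")
        # strictly increasing visit times within patient
        t = self.visits.sort_index().groupby("patient_id", sort=False)["t_years"]
        if (t.diff().dropna() <= 0).any():
            raise CohortError("visit times must be strictly increasing per patient")

    # -- conveniences -----------------------------------------------------
    @property
    def n_patients(self) -> int:
        return len(self.baselines)

    @property
    def n_visits(self) -> int:
        return len(self.visits)

    def patient_ids(self) -> list:
        return list(self.baselines["patient_id"])

    def subset(self, patient_ids: Iterable) -> "LongCohort":
        """Cohort restricted to the given patients (all their visits kept)."""
        keep = set(patient_ids)
        return LongCohort(
            self.baselines[self.baselines["patient_id"].isin(keep)].copy(),
            self.visits[self.visits["patient_id"].isin(keep)].copy(),
        )

    def merged(self) -> pd.DataFrame:
        """Visit table with baseline covariates joined on (one row per visit)."""
        return self.visits.merge(self.baselines, on="patient_id", how="left", sort=False)

    def copy(self) -> "LongCohort":
        return LongCohort(self.baselines.copy(), self.visits.copy())

    # -- CSV interchange --------------------------------------------------
    def to_long_frame(self) -> pd.DataFrame:
        long = self.merged()
        return long[COHORT_COLUMNS]

    def to_csv(self, path: str | Path | io.TextIOBase) -> None:
        self.to_long_frame().to_csv(path, index=False, na_rep="")

    @classmethod
    def from_long_frame(cls, long: pd.DataFrame) -> "LongCohort":
        missing = [c for c in COHORT_COLUMNS if c not in long.columns]
        if missing:
            raise CohortError(f"cohort table missing column {missing[0]!r}")
        extra = [c for c in long.columns if c not in COHORT_COLUMNS]
        if extra:
            raise CohortError(f"cohort table has unexpected column {extra[0]!r}")
        baselines = (
            long[BASELINE_COLUMNS].drop_duplicates(subset="patient_id").reset_index(drop=True)
        )
        visits = long[VISIT_COLUMNS].reset_index(drop=True)
        return cls(baselines, visits)

    @classmethod
    def from_csv(cls, path: str | Path | io.TextIOBase) -> "LongCohort":
        try:
            long = pd.read_csv(path, dtype={"patient_id": str})
        except Exception as exc:  # pragma: no cover - pandas error text varies
            raise CohortError(f"could not parse cohort CSV: {exc}") from exc
        return cls.from_long_frame(long)

    @classmethod
    def empty(cls) -> "LongCohort":
        return cls(
            pd.DataFrame(columns=BASELINE_COLUMNS),
            pd.DataFrame(columns=VISIT_COLUMNS),
        )

    @classmethod
    def from_records(
        cls, baselines: Iterable[PatientBaseline], visits: Iterable[VisitRecord]
    ) -> "LongCohort":
        brows = [
            {
                "patient_id": b.patient_id,
                "sex": b.sex,
                "age0": b.age0,
                "height_m": b.height,
                "creatinine0": np.nan if b.creatinine0 is None else b.creatinine0,
                "egfr0": b.egfr0,
                "httkv0": b.httkv0,
                "true_growth_rate": np.nan if b.true_growth_rate is None else b.true_growth_rate,
            }
            for b in baselines
        ]
        vrows = [
            {
                "patient_id": v.patient_id,
                "t_years": v.t,
                "egfr_obs": v.egfr_obs,
                "httkv": np.nan if v.httkv is None else v.httkv,
            }
            for v in visits
        ]
        if not brows:
            return cls.empty()
        return cls(pd.DataFrame(brows), pd.DataFrame(vrows))


def sex_indicator(sex: pd.Series | np.ndarray | str) -> np.ndarray | float:
    """Numeric sex coding used throughout the models: female = 1, male = 0."""
    if isinstance(sex, str):
        return 1.0 if sex == "female" else 0.0
    return (np.asarray(sex) == "female").astype(float)
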