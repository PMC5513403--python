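"""Mayo 1A-1E risk subclassification from age and height-adjusted TKV.

The classification assumes exponential kidney growth from a theoretical
HtTKV of 150 ml/m at birth: a patient of age ``a`` with HtTKV ``v`` is
assigned the growth rate ``r`` solving 150 * (1+r)^a = v, and the rate is
binned into five ordinal subclasses at 1.5, 3.0, 4.5 and 6 %/yr.  Class
boundaries in HtTKV are therefore age-dependent exponential curves.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

CLASS_LABELS = ["1A", "1B", "1C", "1D", "1E"]

#: Lower rate bound of each class (fraction/yr); intervals are left-closed,
#: so a rate of exactly 0.015 falls in 1B.
CLASS_LOWER_BOUNDS = [-np.inf, 0.015, 0.030, 0.045, 0.060]

#: Default theoretical HtTKV at birth (ml/m), exposed as a parameter.
HTTKV_BIRTH = 150.0


class RiskError(ValueError):
    """Raised on invalid inputs to the risk classification."""


@dataclass(frozen=True, order=True)
class RiskClass:
    """One of the five ordinal subclasses, with its rate interval."""

    index: int  # 0..4, gives the ordinal ordering 1A < ... < 1E
    label: str = ""

    @property
    def rate_interval(self) -> tuple[float, float]:
        hi = CLASS_LOWER_BOUNDS[self.index + 1] if self.index < 4 else np.inf
        return (CLASS_LOWER_BOUNDS[self.index], hi)


def _risk_class(index: int) -> RiskClass:
    return RiskClass(index=index, label=CLASS_LABELS[index])


def estimated_growth_rate(httkv, age, httkv_birth: float = HTTKV_BIRTH):
    """Yearly fractional kidney growth implied by a single age/HtTKV pair.

    Solves httkv_birth * (1+r)^age = httkv for r.  Vectorized over numpy
    arrays.
    """
    httkv = np.asarray(httkv, dtype=float)
    age = np.asarray(age, dtype=float)
    if np.any(age <= 0):
        raise RiskError("age must be positive")
    if np.any(httkv <= 0):
        raise RiskError("HtTKV must be positive")
    rate = np.power(httkv / httkv_birth, 1.0 / age) - 1.0
    return float(rate) if rate.ndim == 0 else rate


def assign_class(rate: float) -> RiskClass:
    """Bin a growth rate into 1A-1E; boundaries belong to the upper class."""
    if not rate > -1:
        raise RiskError("growth rate must exceed -1")
    idx = int(np.searchsorted(CLASS_LOWER_BOUNDS[1:], rate, side="right"))
    return _risk_class(idx)


def classify(httkv, age, httkv_birth: float = HTTKV_BIRTH) -> RiskClass:
    """Convenience: class from a single age/HtTKV pair."""
    return assign_class(float(estimated_growth_rate(httkv, age, httkv_birth)))


def class_boundary_httkv(age, rate_threshold: float, httkv_birth: float = HTTKV_BIRTH):
    """HtTKV on the class-boundary curve at a given age and rate threshold."""
    age = np.asarray(age, dtype=float)
    if np.any(age <= 0):
        raise RiskError("age must be positive")
    out = httkv_birth * np.power(1.0 + rate_threshold, age)
    return float(out) if out.ndim == 0 else out


def boundary_table(ages, httkv_birth: float = HTTKV_BIRTH) -> pd.DataFrame:
    """Boundary curves over an age grid for the four class thresholds."""
    ages = np.asarray(ages, dtype=float)
    out = pd.DataFrame({"age": ages})
    for thr in CLASS_LOWER_BOUNDS[1:]:
        out[f"httkv_at_{thr * 100:.1f}pct"] = class_boundary_httkv(ages, thr, httkv_birth)
    return out


@dataclass
class TransitionSummary:
    """5x5 baseline-class by final-class counts over follow-up.

    ``pct_progressed`` counts patients whose final class is strictly more
    severe than their baseline class; NaN when no patient could be assessed.
    """

    counts: np.ndarray
    n_assessed: int

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.shape != (5, 5):
            raise RiskError("transition counts must be 5x5")
        if self.counts.sum() != self.n_assessed:
            raise RiskError("transition counts must sum to n_assessed")

    @property
    def pct_progressed(self) -> float:
        if self.n_assessed == 0:
            return float("nan")
        return 100.0 * float(np.triu(self.counts, k=1).sum()) / self.n_assessed

    @property
    def pct_regressed(self) -> float:
        if self.n_assessed == 0:
            return float("nan")
        return 100.0 * float(np.tril(self.counts, k=-1).sum()) / self.n_assessed

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=CLASS_LABELS, columns=CLASS_LABELS)


def transition_summary(cohort, httkv_birth: float = HTTKV_BIRTH) -> TransitionSummary:
    """Class transitions from baseline to each patient's last measured HtTKV.

    The baseline class uses (httkv0, age0); the final class uses the last
    follow-up visit with a non-missing HtTKV, at age age0 + t.  Patients
    with no measured follow-up HtTKV are excluded from n_assessed.
    """
    counts = np.zeros((5, 5), dtype=int)
    merged = cohort.merged()
    measured = merged.dropna(subset=["httkv"])
    last = measured.sort_values("t_years", kind="stable").groupby("patient_id", sort=False).last()
    for _, row in last.iterrows():
        c0 = classify(row["httkv0"], row["age0"], httkv_birth)
        c1 = classify(row["httkv"], row["age0"] + row["t_years"], httkv_birth)
        counts[c0.index, c1.index] += 1
    return TransitionSummary(counts=counts, n_assessed=int(counts.sum()))


def classify_cohort(cohort, httkv_birth: float = HTTKV_BIRTH) -> pd.DataFrame:
    """Per-patient baseline and last-visit growth rates and classes."""
    merged = cohort.merged()
    rows = []
    measured = merged.dropna(subset=["httkv"])
    last = measured.sort_values("t_years", kind="stable").groupby("patient_id", sort=False).last()
    for _, b in cohort.baselines.iterrows():
        rate0 = float(estimated_growth_rate(b["httkv0"], b["age0"], httkv_birth))
        rec = {
            "patient_id": b["patient_id"],
            "rate0": rate0,
            "class0": assign_class(rate0).label,
            "rate_last": np.nan,
            "class_last": "",
        }
        if b["patient_id"] in last.index:
            lrow = last.loc[b["patient_id"]]
            rate1 = float(
                estimated_growth_rate(lrow["httkv"], b["age0"] + lrow["t_years"], httkv_birth)
            )
            rec["rate_last"] = rate1
            rec["class_last"] = assign_class(rate1).label
        rows.append(rec)
    return pd.DataFrame(rows, columns=["patient_id", "rate0", "class0", "rate_last", "class_last"])
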