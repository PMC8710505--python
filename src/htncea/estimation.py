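"""Estimation of model parameters from longitudinal follow-up records.

A trial cohort is a table of patient-visit rows (see
:data:`RECORD_COLUMNS`): one baseline visit (index 0) and up to twelve
bi-monthly follow-ups, each with blood pressure, the assigned
hypertension level, and the eight SF-36 dimension scores.  From such a
table this module estimates

* annual transition probabilities between blood-pressure levels, via the
  study-probability -> study-rate -> annual-probability conversion,
* arm-level blood-pressure control rates (SBP strictly below 120 mmHg),
* per-state EQ-5D utilities mapped from SF-36 dimension scores, and
* inflation/currency-adjusted costs, including salary-based labour cost.

The transition estimator follows the trial's own convention: one
transition per patient (baseline level vs. final-visit level) and a
study probability whose denominator is the *whole* analyzable cohort,
not the number of patients starting in the origin level.  A per-origin
denominator is available behind ``denominator="origin"`` for users who
prefer the conventional row-conditional estimate.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .states import HYPERTENSION_STATES, NORMOTENSION, PREHYPERTENSION, RECORD_STATES

logger = logging.getLogger(__name__)

#: follow-up record CSV schema (SF-36 dimensions in lower case)
RECORD_COLUMNS = (
    "patient_id", "arm", "visit_index", "sbp", "dbp", "state",
    "pf", "rp", "bp", "gh", "vt", "sf", "re", "mh",
)
SF36_DIMENSIONS = ("pf", "rp", "bp", "gh", "vt", "sf", "re", "mh")

#: published SF-36 -> EQ-5D mapping (Ara & Brazier model 1): intercept and
#: one coefficient per dimension on the 0-100 scale.
SF36_EQ5D_INTERCEPT = 0.03256
SF36_EQ5D_COEFFS = {
    "pf": 0.0037,
    "sf": 0.00111,
    "rp": -0.00024,
    "re": 0.00024,
    "mh": 0.00256,
    "vt": -0.00063,
    "bp": 0.00286,
    "gh": 0.00052,
}


class EstimationError(ValueError):
    """Invalid input to an estimation routine."""


@dataclass(frozen=True)
class StudyWindow:
    """Observation window length t (years) behind a study probability."""

    duration_years: float = 2.0

    def __post_init__(self):
        if self.duration_years <= 0:
            raise EstimationError("study window must be positive")


@dataclass
class TransitionCountTable:
    """Per-patient baseline->final transition counts over the whole cohort.

    ``counts`` maps (origin, destination) level pairs to patient counts;
    ``total_n`` is the analyzable cohort size used as the denominator of
    every study probability.
    """

    counts: dict[tuple[str, str], int] = field(default_factory=dict)
    total_n: int = 0

    def __post_init__(self):
        if any(c < 0 for c in self.counts.values()):
            raise EstimationError("transition counts must be non-negative")
        if self.counts and sum(self.counts.values()) != self.total_n:
            raise EstimationError("counts must sum to total_n")

    def count(self, origin: str, destination: str) -> int:
        return self.counts.get((origin, destination), 0)


@dataclass(frozen=True)
class ControlRateEstimate:
    arm: str
    control_rate: float
    n_measurements: int

    def __post_init__(self):
        if not 0.0 <= self.control_rate <= 1.0:
            raise EstimationError("control rate must lie in [0, 1]")


@dataclass(frozen=True)
class CostAdjustment:
    """Inflation and currency adjustment to a base year."""

    record_year: int
    base_year: int = 2021
    inflation_rate: float = 0.025
    exchange_rate: float = 0.156  # USD per CNY

    def __post_init__(self):
        if self.base_year < self.record_year:
            raise EstimationError("base_year must not precede record_year")
        if self.inflation_rate < 0 or self.exchange_rate <= 0:
            raise EstimationError("invalid inflation or exchange rate")


@dataclass(frozen=True)
class SalaryInputs:
    """Inputs to the human-capital labour-cost formula."""

    mean_annual_salary: float = 17979.40  # USD/year
    working_days: float = 250.0
    hours_per_day: float = 8.0
    additional_hours: float = 0.0

    def __post_init__(self):
        if min(self.mean_annual_salary, self.working_days, self.hours_per_day) <= 0:
            raise EstimationError("salary inputs must be strictly positive")


# --- rate/probability conversions ----------------------------------------

def study_probability(
    counts: TransitionCountTable,
    origin: str,
    destination: str,
    denominator: str = "cohort",
) -> float:
    """Observed transition frequency over the study window.

    With the default ``denominator="cohort"`` the frequency is
    count / total_n exactly as the trial tabulates it; with
    ``"origin"`` the denominator is the number of patients whose
    baseline level is ``origin``.
    """
    if counts.total_n <= 0:
        raise EstimationError("count table has no patients")
    c = counts.count(origin, destination)
    if denominator == "cohort":
        return c / counts.total_n
    if denominator == "origin":
        n_origin = sum(v for (o, _), v in counts.counts.items() if o == origin)
        if n_origin == 0:
            raise EstimationError(f"no patients start in state {origin!r}")
        return c / n_origin
    raise EstimationError(f"unknown denominator convention {denominator!r}")


def probability_to_rate(p: float, t: float) -> float:
    """Constant hazard implied by probability ``p`` over ``t`` years."""
    if t <= 0:
        raise EstimationError("t must be positive")
    if p < 0:
        raise EstimationError("probability must be non-negative")
    if p >= 1:
        raise EstimationError("probability 1 implies an infinite rate")
    return -math.log1p(-p) / t


def rate_to_annual_probability(rate: float) -> float:
    """1-year probability implied by a constant annual ``rate``."""
    if rate < 0:
        raise EstimationError("rate must be non-negative")
    return -math.expm1(-rate)


def annualize_study_probability(p: float, t: float) -> float:
    """Convert a ``t``-year observed probability to a 1-year probability."""
    return rate_to_annual_probability(probability_to_rate(p, t))


# --- transition counting --------------------------------------------------

def count_transitions(
    records: pd.DataFrame, n_visits: int = 12
) -> TransitionCountTable:
    """One baseline->final transition per patient, over all arms pooled.

    Patients lacking either the baseline visit (index 0) or the final
    visit (index ``n_visits``) are excluded (logged at INFO level).
    """
    _require_columns(records, ("patient_id", "visit_index", "state"))
    base = records[records["visit_index"] == 0].set_index("patient_id")["state"]
    final = records[records["visit_index"] == n_visits].set_index("patient_id")["state"]
    complete = base.index.intersection(final.index)
    n_excluded = len(base.index.union(final.index)) - len(complete)
    if n_excluded:
        logger.info("excluded %d patients missing baseline or final visit", n_excluded)
    pairs = pd.DataFrame({"origin": base.loc[complete], "destination": final.loc[complete]})
    counts = pairs.value_counts().to_dict()
    return TransitionCountTable(counts={k: int(v) for k, v in counts.items()},
                                total_n=int(len(complete)))


def annual_transition_probabilities(
    counts: TransitionCountTable,
    window: StudyWindow = StudyWindow(2.0),
    normotension: str = "drop",
    denominator: str = "cohort",
) -> dict[tuple[str, str], float]:
    """Annual probabilities for every off-diagonal blood-pressure pair.

    ``normotension`` controls what happens to transitions recorded into
    the normotension state (which the model cannot occupy):
    ``"drop"`` ignores them, exactly as the source tabulation does;
    ``"fold"`` merges them into prehypertension before annualization.
    """
    if normotension not in ("drop", "fold"):
        raise EstimationError(f"unknown normotension policy {normotension!r}")
    merged: dict[tuple[str, str], int] = {}
    for (o, d), c in counts.counts.items():
        if o == NORMOTENSION:
            continue  # the model never starts a cycle in normotension
        if d == NORMOTENSION:
            if normotension == "drop":
                continue
            d = PREHYPERTENSION
        merged[(o, d)] = merged.get((o, d), 0) + c
    if counts.total_n <= 0:
        raise EstimationError("count table has no patients")
    out: dict[tuple[str, str], float] = {}
    for o in HYPERTENSION_STATES:
        if denominator == "cohort":
            denom = counts.total_n
        elif denominator == "origin":
            denom = sum(v for (oo, _), v in counts.counts.items() if oo == o)
        else:
            raise EstimationError(f"unknown denominator convention {denominator!r}")
        for d in HYPERTENSION_STATES:
            if o == d:
                continue
            c = merged.get((o, d), 0)
            p = c / denom if denom else 0.0
            out[(o, d)] = annualize_study_probability(p, window.duration_years)
    return out


# --- effectiveness --------------------------------------------------------

def estimate_control_rate(records: pd.DataFrame, arm: str) -> ControlRateEstimate:
    """Fraction of post-baseline SBP measurements strictly below 120 mmHg.

    Measurements are pooled over all patients and follow-ups in the arm;
    the baseline visit is excluded because it precedes the intervention.
    """
    _require_columns(records, ("arm", "visit_index", "sbp"))
    sel = records[(records["arm"] == arm) & (records["visit_index"] >= 1)]
    if sel.empty:
        raise EstimationError(f"arm {arm!r} has no post-baseline measurements")
    controlled = (sel["sbp"] < 120.0).mean()
    return ControlRateEstimate(arm=arm, control_rate=float(controlled),
                               n_measurements=int(len(sel)))


def estimate_control_rate_per_patient(records: pd.DataFrame, arm: str) -> ControlRateEstimate:
    """Alternative estimator: per-patient control fractions, then averaged."""
    _require_columns(records, ("arm", "visit_index", "sbp", "patient_id"))
    sel = records[(records["arm"] == arm) & (records["visit_index"] >= 1)]
    if sel.empty:
        raise EstimationError(f"arm {arm!r} has no post-baseline measurements")
    per_patient = (sel["sbp"] < 120.0).groupby(sel["patient_id"]).mean()
    return ControlRateEstimate(arm=arm, control_rate=float(per_patient.mean()),
                               n_measurements=int(len(sel)))


# --- utilities ------------------------------------------------------------

def map_sf36_to_eq5d(sf36, clamp_negative: bool = True) -> float:
    """EQ-5D index predicted from the eight SF-36 dimension scores.

    ``sf36`` is a mapping with keys pf, rp, bp, gh, vt, sf, re, mh
    (case-insensitive) or a sequence of eight scores in that order.
    The published linear model can predict outside [0, 1] at the scale
    extremes; negative predictions are clamped to 0 (with a warning) so
    QALY weights stay well-defined, values above 1 are returned as-is.
    """
    if not hasattr(sf36, "keys"):
        sf36 = dict(zip(SF36_DIMENSIONS, sf36))
    scores = {str(k).lower(): float(v) for k, v in sf36.items()}
    missing = [d for d in SF36_DIMENSIONS if d not in scores]
    if missing:
        raise EstimationError(f"missing SF-36 dimensions: {missing}")
    for d in SF36_DIMENSIONS:
        if not 0.0 <= scores[d] <= 100.0:
            raise EstimationError(f"SF-36 {d} score {scores[d]} outside [0, 100]")
    value = SF36_EQ5D_INTERCEPT + sum(
        SF36_EQ5D_COEFFS[d] * scores[d] for d in SF36_DIMENSIONS
    )
    if value < 0 and clamp_negative:
        warnings.warn("mapped EQ-5D below 0 clamped to 0", stacklevel=2)
        return 0.0
    return value


def estimate_state_utility(
    records: pd.DataFrame, state: str
) -> tuple[float, tuple[float, float]]:
    """Mean mapped utility of records in ``state`` with a normal 95% CI."""
    _require_columns(records, ("state",) + SF36_DIMENSIONS)
    sel = records[records["state"] == state]
    if len(sel) < 2:
        raise EstimationError(
            f"need at least 2 records in state {state!r} for a confidence interval"
        )
    scores = sel[list(SF36_DIMENSIONS)].to_numpy(dtype=float)
    coeffs = np.array([SF36_EQ5D_COEFFS[d] for d in SF36_DIMENSIONS])
    utils = SF36_EQ5D_INTERCEPT + scores @ coeffs
    utils = np.clip(utils, 0.0, None)
    mean = float(utils.mean())
    half = 1.96 * float(utils.std(ddof=1)) / math.sqrt(len(utils))
    return mean, (mean - half, mean + half)


# --- costs ----------------------------------------------------------------

def adjust_cost(amount: float, adj: CostAdjustment, currency: str = "USD") -> float:
    """Inflate ``amount`` to the base year; convert CNY to USD first."""
    if amount < 0:
        raise EstimationError("cost must be non-negative")
    if currency.upper() == "CNY":
        amount = amount * adj.exchange_rate
    elif currency.upper() != "USD":
        raise EstimationError(f"unknown currency {currency!r}")
    return amount * (1.0 + adj.inflation_rate) ** (adj.base_year - adj.record_year)


def salary_cost(inputs: SalaryInputs) -> float:
    """Labour cost of additional working time at the mean hourly salary."""
    hourly = inputs.mean_annual_salary / inputs.working_days / inputs.hours_per_day
    return hourly * inputs.additional_hours


def _require_columns(df: pd.DataFrame, cols) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise EstimationError(f"records missing columns: {missing}")


def validate_records(records: pd.DataFrame, check_bands: bool = False) -> None:
    """Raise on structurally invalid follow-up records.

    Checks visit uniqueness per patient, sbp > dbp > 0, SF-36 ranges and
    recognized state labels.  ``check_bands=True`` additionally requires
    the recorded state to match the blood-pressure cutpoints, except for
    controlled measurements (SBP < 120) which may sit below the band of
    an uncontrolled underlying level.
    """
    _require_columns(records, RECORD_COLUMNS)
    if records.duplicated(["patient_id", "visit_index"]).any():
        raise EstimationError("duplicate visit_index within a patient")
    if not ((records["sbp"] > records["dbp"]) & (records["dbp"] > 0)).all():
        raise EstimationError("require sbp > dbp > 0 in every record")
    scores = records[list(SF36_DIMENSIONS)]
    if ((scores < 0) | (scores > 100)).any().any():
        raise EstimationError("SF-36 scores must lie in [0, 100]")
    bad = set(records["state"]) - set(RECORD_STATES)
    if bad:
        raise EstimationError(f"unknown state labels: {sorted(bad)}")
    if check_bands:
        from .states import BP_BANDS

        for state, grp in records.groupby("state"):
            lo, hi, *_ = BP_BANDS[state]
            ok = ((grp["sbp"] >= lo) & (grp["sbp"] <= hi)) | (grp["sbp"] < 120.0)
            if not ok.all():
                raise EstimationError(f"SBP outside the {state} band")
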