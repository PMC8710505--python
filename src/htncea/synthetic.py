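"""Synthetic longitudinal trial generator with known ground truth.

Emulates a three-arm community hypertension-management trial: each arm
enrols a cohort whose baseline blood-pressure levels follow the trial's
observed mix (0.32 / 0.53 / 0.12 / 0.03 over prehypertension and
hypertension L1-L3), followed up every two months for two years
(12 follow-ups).  Levels evolve by a known 2-month Markov matrix;
blood pressure is emitted within the occupied level's cutpoint band,
except that each post-baseline visit is "controlled" (SBP drawn below
120 mmHg) with the arm's configured control frequency; the eight SF-36
dimension scores are drawn around state-specific means whose mapped
EQ-5D utilities equal the published per-state values; drop-out
truncates records at a per-visit rate calibrated to the trial's 12.63%
overall loss to follow-up.  Output is the same record table the
estimation module consumes, and generation is deterministic given the
seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .estimation import (
    EstimationError,
    SF36_DIMENSIONS,
    SF36_EQ5D_COEFFS,
    SF36_EQ5D_INTERCEPT,
)
from .states import BP_BANDS, HYPERTENSION_STATES

#: overall loss to follow-up the default per-visit drop-out reproduces
DEFAULT_OVERALL_DROPOUT = 0.1263

DEFAULT_BASELINE = {"prehypertension": 0.32, "L1": 0.53, "L2": 0.12, "L3": 0.03}
DEFAULT_CONTROL_RATES = {"option1": 0.62, "option2": 0.69, "usual": 0.61}
#: published per-state utilities the default SF-36 means map to
DEFAULT_STATE_UTILITIES = {
    "prehypertension": 0.651375, "L1": 0.65525, "L2": 0.683, "L3": 0.669,
}

_SLOPE_SUM = sum(SF36_EQ5D_COEFFS.values())


def sf36_means_for_utility(utility: float) -> np.ndarray:
    """Equal-dimension SF-36 mean vector whose mapped EQ-5D is ``utility``."""
    level = (utility - SF36_EQ5D_INTERCEPT) / _SLOPE_SUM
    if not 0.0 <= level <= 100.0:
        raise EstimationError(f"utility {utility} unreachable with in-range scores")
    return np.full(len(SF36_DIMENSIONS), level)


def per_visit_dropout(overall: float, n_visits: int = 12) -> float:
    """Per-visit drop-out probability giving ``overall`` loss by the end."""
    if not 0.0 <= overall < 1.0:
        raise EstimationError("overall drop-out must lie in [0, 1)")
    return 1.0 - (1.0 - overall) ** (1.0 / n_visits)


def annual_to_step_probability(p_annual: float, step_years: float) -> float:
    """Probability over a sub-annual step with the same constant hazard.

    Composing ``1/step_years`` steps recovers the annual probability.
    """
    if not 0.0 <= p_annual < 1.0:
        raise EstimationError("annual probability must lie in [0, 1)")
    if step_years <= 0:
        raise EstimationError("step must be positive")
    return -math.expm1(step_years * math.log1p(-p_annual))


def step_matrix_from_annual(
    annual: dict[tuple[str, str], float], step_years: float = 1.0 / 6.0
) -> np.ndarray:
    """4x4 row-stochastic 2-month matrix over the blood-pressure levels.

    Off-diagonal annual probabilities are converted cell-wise to the
    step length; the diagonal takes the residual.
    """
    n = len(HYPERTENSION_STATES)
    m = np.zeros((n, n))
    for i, o in enumerate(HYPERTENSION_STATES):
        for j, d in enumerate(HYPERTENSION_STATES):
            if o != d:
                m[i, j] = annual_to_step_probability(
                    annual.get((o, d), 0.0), step_years
                )
        resid = 1.0 - m[i].sum()
        if resid < 0:
            raise EstimationError(f"step probabilities from {o} exceed 1")
        m[i, i] = resid
    return m


def default_step_matrix() -> np.ndarray:
    """2-month matrix implied by the packaged annual level-to-level rows."""
    from .io import load_packaged_arm

    ps = load_packaged_arm("usual")
    annual = {
        (o, d): p
        for (o, d), p in ps.transitions.items()
        if o in HYPERTENSION_STATES and d in HYPERTENSION_STATES
    }
    return step_matrix_from_annual(annual)


@dataclass
class GeneratorConfig:
    """Study conditions of the emulated trial; the defaults are the
    published ones (cohort size, baseline mix, control rates, follow-up
    schedule, loss to follow-up)."""

    seed: int
    n_per_arm: int = 416  # ~1,248 analyzable patients over three arms
    n_visits: int = 12
    visit_interval_years: float = 1.0 / 6.0
    baseline_distribution: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BASELINE)
    )
    step_matrix: np.ndarray | None = None  # default: packaged annual rows
    control_rates: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CONTROL_RATES)
    )
    state_utilities: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_STATE_UTILITIES)
    )
    sf36_noise_sd: float = 10.0
    dropout_per_visit: float = per_visit_dropout(DEFAULT_OVERALL_DROPOUT)

    def __post_init__(self):
        probs = [self.baseline_distribution.get(s, 0.0) for s in HYPERTENSION_STATES]
        if any(p < 0 for p in probs) or abs(sum(probs) - 1.0) > 1e-9:
            raise EstimationError("baseline distribution must be a probability vector")
        if not 0.0 <= self.dropout_per_visit < 1.0:
            raise EstimationError("per-visit drop-out must lie in [0, 1)")
        for arm, r in self.control_rates.items():
            if not 0.0 <= r <= 1.0:
                raise EstimationError(f"control rate of {arm} outside [0, 1]")


def generate_cohort(config: GeneratorConfig) -> pd.DataFrame:
    """Simulate the trial and return the follow-up record table.

    One row per patient-visit with columns patient_id, arm,
    visit_index, sbp, dbp, state and the eight SF-36 scores; byte-level
    deterministic for a given config.
    """
    rng = np.random.default_rng(config.seed)
    step = config.step_matrix if config.step_matrix is not None else default_step_matrix()
    step = np.asarray(step, dtype=float)
    if step.shape != (4, 4) or (step < 0).any() or not np.allclose(step.sum(axis=1), 1.0):
        raise EstimationError("step matrix must be 4x4 row-stochastic")
    baseline_p = np.array(
        [config.baseline_distribution.get(s, 0.0) for s in HYPERTENSION_STATES]
    )
    means = {
        s: sf36_means_for_utility(u) for s, u in config.state_utilities.items()
    }
    frames = []
    for arm in sorted(config.control_rates):
        control = config.control_rates[arm]
        n = config.n_per_arm
        states = rng.choice(4, size=n, p=baseline_p)  # baseline levels
        # visit after which each patient is lost (n_visits = completer)
        if config.dropout_per_visit > 0:
            last_visit = np.minimum(
                rng.geometric(config.dropout_per_visit, size=n), config.n_visits
            )
        else:
            last_visit = np.full(n, config.n_visits)
        for visit in range(config.n_visits + 1):
            if visit > 0:
                # evolve every patient; rows of lost patients are dropped below
                nxt = np.empty_like(states)
                for k in range(4):
                    mask = states == k
                    if mask.any():
                        nxt[mask] = rng.choice(4, size=mask.sum(), p=step[k])
                states = nxt
            present = last_visit >= visit
            controlled = (
                (rng.random(n) < control) & present if visit > 0 else np.zeros(n, bool)
            )
            sbp = np.empty(n)
            dbp = np.empty(n)
            for k, state in enumerate(HYPERTENSION_STATES):
                lo_s, hi_s, lo_d, hi_d = BP_BANDS[state]
                mask = states == k
                sbp[mask] = rng.uniform(lo_s, hi_s, size=mask.sum())
                dbp[mask] = rng.uniform(lo_d, hi_d, size=mask.sum())
            sbp[controlled] = rng.uniform(90.0, 119.9, size=int(controlled.sum()))
            dbp[controlled] = rng.uniform(60.0, 79.9, size=int(controlled.sum()))
            sf36 = np.empty((n, len(SF36_DIMENSIONS)))
            for k, state in enumerate(HYPERTENSION_STATES):
                mask = states == k
                noise = rng.normal(0.0, config.sf36_noise_sd,
                                   size=(int(mask.sum()), len(SF36_DIMENSIONS)))
                sf36[mask] = np.clip(means[state] + noise, 0.0, 100.0)
            frame = pd.DataFrame(
                {
                    "patient_id": [f"{arm}-{i:05d}" for i in range(n)],
                    "arm": arm,
                    "visit_index": visit,
                    "sbp": np.round(sbp, 1),
                    "dbp": np.round(dbp, 1),
                    "state": [HYPERTENSION_STATES[k] for k in states],
                }
            )
            for j, dim in enumerate(SF36_DIMENSIONS):
                frame[dim] = np.round(sf36[:, j], 1)
            frames.append(frame[present])
    records = pd.concat(frames, ignore_index=True)
    return records.sort_values(["arm", "patient_id", "visit_index"]).reset_index(
        drop=True
    )


def expected_study_probabilities(
    config: GeneratorConfig,
) -> dict[tuple[str, str], float]:
    """Analytic expectation of each baseline-to-final study probability.

    Independent of any estimator: the expected whole-cohort frequency of
    (baseline level i, final level j) is pi_i * (M^v)_ij with M the
    2-month matrix and v the number of follow-ups.
    """
    step = config.step_matrix if config.step_matrix is not None else default_step_matrix()
    power = np.linalg.matrix_power(np.asarray(step, float), config.n_visits)
    pi = np.array([config.baseline_distribution.get(s, 0.0) for s in HYPERTENSION_STATES])
    return {
        (o, d): float(pi[i] * power[i, j])
        for i, o in enumerate(HYPERTENSION_STATES)
        for j, d in enumerate(HYPERTENSION_STATES)
    }
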