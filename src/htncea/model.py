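"""Nine-state annual-cycle Markov cohort engine.

The cohort starts distributed over the four blood-pressure levels and
is pushed through a row-stochastic 9x9 matrix once per 1-year cycle for
a lifetime horizon (65 cycles by default).  The matrix is rebuilt each
cycle because background mortality is age-dependent; everything else is
time-homogeneous.  Rewards (costs, QALYs, life-years) accrue on the
state occupied at the start of a cycle and are discounted at
1/(1+r)^cycle, the first model year being undiscounted.  No half-cycle
correction is applied by default (``half_cycle=True`` enables the
standard correction).

The strategy arms differ through their blood-pressure control rate.
The arm effect enters by scaling every *improvement* transition (a move
to a strictly less severe blood-pressure level) by the ratio of the
arm's control rate to the usual-practice reference rate; the change is
absorbed into the origin state's residual stay probability, so rows
stay stochastic and the usual arm reproduces the estimated matrix
unchanged.  Alternative mechanisms can be supplied via the
``arm_effect`` hook of :func:`build_transition_matrix`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, NamedTuple

import numpy as np
import pandas as pd

from .params import ArmParameters, MortalityTable, ParameterError, ParameterSet
from .states import DEATH, N_STATES, STATE_INDEX, STATES, is_improvement

_DEATH_IDX = STATE_INDEX[DEATH]


class Totals(NamedTuple):
    """Discounted lifetime totals per person entering the model."""

    cost: float
    ly: float
    qaly: float


@dataclass
class CohortTrace:
    """Per-cycle occupancy and reward increments for one arm.

    ``trace`` has one row per cycle (plus the initial row) with the nine
    state occupancies and the undiscounted/discounted cost, QALY and
    life-year increments of that cycle.
    """

    arm: str
    trace: pd.DataFrame

    @property
    def fraction_dead(self) -> float:
        """Death-state occupancy after the final cycle."""
        return float(self.trace[DEATH].iloc[-1])

    @property
    def totals(self) -> Totals:
        t = self.trace
        return Totals(
            cost=float(t["disc_cost"].sum()),
            ly=float(t["disc_ly"].sum()),
            qaly=float(t["disc_qaly"].sum()),
        )

    @property
    def undiscounted_ly(self) -> float:
        return float(self.trace["ly"].sum())


def mortality_lookup(table: MortalityTable, age: float) -> float:
    """Annual natural-death probability for ``age`` (35 and over)."""
    return table.lookup(age)


def discount_factor(rate: float, cycle: int) -> float:
    """1/(1+rate)^cycle; cycle 0 (the first model year) is undiscounted."""
    if cycle < 0:
        raise ParameterError("cycle must be non-negative")
    return 1.0 / (1.0 + rate) ** cycle


def default_arm_effect(
    origin: str, destination: str, p: float, arm: ArmParameters, reference: float
) -> float:
    """Scale improvement transitions by control_rate / reference rate."""
    if is_improvement(origin, destination):
        return p * arm.control_rate / reference
    return p


def build_transition_matrix(
    transitions: dict[tuple[str, str], float],
    mortality: MortalityTable,
    age: float,
    arm: ArmParameters,
    reference_control_rate: float,
    arm_effect: Callable[..., float] = default_arm_effect,
) -> np.ndarray:
    """Row-stochastic 9x9 matrix for one cycle at the given age.

    Each non-death row carries the listed annual transition
    probabilities (improvement moves rescaled by ``arm_effect``), the
    age-band natural mortality added to any disease-specific death
    probability, and a residual self-transition.  The death row is the
    identity.
    """
    q_nat = mortality.lookup(age)
    m = np.zeros((N_STATES, N_STATES))
    for origin in STATES:
        i = STATE_INDEX[origin]
        if origin == DEATH:
            m[i, i] = 1.0
            continue
        for destination in STATES:
            if destination == origin:
                continue
            p = transitions.get((origin, destination), 0.0)
            if p:
                p = arm_effect(origin, destination, p, arm, reference_control_rate)
            m[i, STATE_INDEX[destination]] = p
        m[i, _DEATH_IDX] += q_nat
        off_diagonal = m[i].sum()
        if off_diagonal > 1.0 + 1e-12:
            raise ParameterError(
                f"row {origin!r} off-diagonal probabilities sum to "
                f"{off_diagonal:.6f} > 1 at age {age}"
            )
        m[i, i] = 1.0 - off_diagonal
    return m


def run_cohort(params: ParameterSet, half_cycle: bool = False) -> CohortTrace:
    """Iterate the cohort over the lifetime horizon for one arm.

    Returns the full per-cycle trace; discounted totals are available as
    ``trace.totals``.  With ``half_cycle`` the reward of each cycle is
    the average of start- and end-of-cycle occupancies.
    """
    econ = params.economics
    occupancy = np.zeros(N_STATES)
    for s, p in econ.initial_distribution.items():
        occupancy[STATE_INDEX[s]] = p

    utility = np.array([params.utilities.get(s, 0.0) for s in STATES])
    state_cost = np.array([params.costs.get(s, 0.0) for s in STATES])
    alive = np.array([s != DEATH for s in STATES], dtype=float)

    rows = []
    m = None
    last_q = None
    for cycle in range(econ.horizon):
        age = econ.start_age + cycle * econ.cycle_length
        q_nat = params.mortality.lookup(age)
        if m is None or q_nat != last_q:  # matrix changes only across age bands
            m = build_transition_matrix(
                params.transitions, params.mortality, age, params.arm,
                econ.reference_control_rate,
            )
            last_q = q_nat
        if not np.allclose(m.sum(axis=1), 1.0, atol=1e-9):
            raise ParameterError(f"non-stochastic matrix at cycle {cycle} (age {age})")
        nxt = occupancy @ m
        reward_occ = 0.5 * (occupancy + nxt) if half_cycle else occupancy
        c_int = params.arm.intervention_cost_at_cycle(cycle)
        cost = float(reward_occ @ (alive * (state_cost + c_int)))
        qaly = float(reward_occ @ utility) * econ.cycle_length
        ly = float(reward_occ @ alive) * econ.cycle_length
        df = discount_factor(econ.discount_rate, cycle)
        rows.append(
            dict(
                cycle=cycle, age=age,
                **{s: occupancy[STATE_INDEX[s]] for s in STATES},
                cost=cost, qaly=qaly, ly=ly,
                disc_cost=cost * df, disc_qaly=qaly * df, disc_ly=ly * df,
            )
        )
        occupancy = nxt

    # terminal row: occupancy after the last transition, no rewards
    rows.append(
        dict(
            cycle=econ.horizon, age=econ.start_age + econ.horizon * econ.cycle_length,
            **{s: occupancy[STATE_INDEX[s]] for s in STATES},
            cost=0.0, qaly=0.0, ly=0.0, disc_cost=0.0, disc_qaly=0.0, disc_ly=0.0,
        )
    )
    return CohortTrace(arm=params.arm.label, trace=pd.DataFrame(rows))


def total_outcomes(trace: CohortTrace) -> Totals:
    """Discounted lifetime (cost, life-years, QALYs) of a trace."""
    return trace.totals
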