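"""Parameter containers for the cohort model.

A :class:`ParameterSet` bundles everything one strategy arm needs to
run: annual transition probabilities (named after the source tables,
p0.5_1 ... pESRD_Death), per-state utilities (U_pre ... U_ESRD), annual
per-state treatment costs (cprehy ... cESRD), the age-band natural
mortality table, arm-level intervention costs and control rate, and the
economic settings (discount rate, willingness to pay, horizon, start
age, initial distribution).  Sensitivity ranges for each named
parameter ride along so the one-way and probabilistic analyses can be
driven from the same file.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace

from .states import (
    CHF,
    DEATH,
    ESRD,
    HYPERTENSION_STATES,
    L1,
    L2,
    L3,
    MI,
    PREHYPERTENSION,
    STATES,
    STROKE,
    parse_transition_symbol,
)


class ParameterError(ValueError):
    """Inconsistent or out-of-range model parameter."""


#: utility symbols per non-death state, as printed
UTILITY_SYMBOLS = {
    "U_pre": PREHYPERTENSION, "U_1": L1, "U_2": L2, "U_3": L3,
    "U_MI": MI, "U_Stroke": STROKE, "U_CHF": CHF, "U_ESRD": ESRD,
}
#: annual treatment-cost symbols per non-death state, as printed
COST_SYMBOLS = {
    "cprehy": PREHYPERTENSION, "chy1": L1, "chy2": L2, "chy3": L3,
    "cMI": MI, "cStroke": STROKE, "cCHF": CHF, "cESRD": ESRD,
}


@dataclass
class MortalityTable:
    """Annual all-cause death probability by 5-year age band (35 to 100+)."""

    bands: dict[int, float]  # lower bound of band -> annual probability

    def __post_init__(self):
        if not self.bands:
            raise ParameterError("mortality table is empty")
        ages = sorted(self.bands)
        if ages[0] != 35:
            raise ParameterError("mortality table must start at age 35")
        for a, b in zip(ages, ages[1:]):
            if b - a != 5:
                raise ParameterError("mortality bands must be contiguous 5-year bands")
        for a, q in self.bands.items():
            if not 0.0 <= q <= 1.0:
                raise ParameterError(f"mortality at age {a} outside [0, 1]")

    def lookup(self, age: float) -> float:
        """Annual death probability of the band containing ``age``.

        Ages at or beyond the last band use the terminal (open-ended) band.
        """
        if age < 35:
            raise ParameterError(f"age {age} below the mortality table (35+)")
        ages = sorted(self.bands)
        band = ages[0]
        for a in ages:
            if age >= a:
                band = a
        return self.bands[band]


@dataclass
class ArmParameters:
    """Strategy-arm effectiveness and intervention-cost inputs.

    ``human_cost`` and ``project_cost`` are trial-scale totals; the
    per-person per-cycle intervention cost divides them by the number of
    enrolled patients and by the intervention span in years.  With
    ``lifelong_programme`` (default) that per-cycle cost recurs every
    model cycle, treating the programme as a permanent service; else it
    applies for ``intervention_cycles`` cycles only.
    """

    label: str
    control_rate: float
    human_cost: float = 0.0
    project_cost: float = 0.0
    n_enrolled: int = 415
    intervention_span_years: float = 1.5
    lifelong_programme: bool = True
    intervention_cycles: int = 2

    def __post_init__(self):
        if not 0.0 <= self.control_rate <= 1.0:
            raise ParameterError("control_rate must lie in [0, 1]")
        if self.human_cost < 0 or self.project_cost < 0:
            raise ParameterError("arm costs must be non-negative")
        if self.n_enrolled <= 0 or self.intervention_span_years <= 0:
            raise ParameterError("n_enrolled and intervention span must be positive")

    @property
    def per_capita_cost_per_cycle(self) -> float:
        """USD per person per model year attributable to the intervention."""
        return (self.human_cost + self.project_cost) / (
            self.n_enrolled * self.intervention_span_years
        )

    def intervention_cost_at_cycle(self, cycle: int) -> float:
        if self.lifelong_programme or cycle < self.intervention_cycles:
            return self.per_capita_cost_per_cycle
        return 0.0


@dataclass
class EconomicSettings:
    discount_rate: float = 0.05
    wtp: float = 1599.16  # USD per QALY per year
    horizon: int = 65  # cycles
    cycle_length: float = 1.0  # years
    start_age: float = 35.0
    initial_distribution: dict[str, float] = field(
        default_factory=lambda: {PREHYPERTENSION: 0.32, L1: 0.53, L2: 0.12, L3: 0.03}
    )
    reference_control_rate: float = 0.61  # usual-practice arm

    def __post_init__(self):
        if not 0.0 <= self.discount_rate <= 0.08:
            raise ParameterError("discount rate outside the supported [0, 0.08] range")
        if self.wtp <= 0:
            raise ParameterError("willingness to pay must be positive")
        if self.horizon < 1:
            raise ParameterError("horizon must be at least one cycle")
        extra = set(self.initial_distribution) - set(HYPERTENSION_STATES)
        if extra:
            raise ParameterError(f"initial distribution over unknown states: {extra}")
        total = sum(self.initial_distribution.values())
        if abs(total - 1.0) > 1e-9:
            raise ParameterError(f"initial distribution sums to {total}, not 1")
        if not 0.0 < self.reference_control_rate <= 1.0:
            raise ParameterError("reference control rate must lie in (0, 1]")


@dataclass
class ParameterSet:
    """Complete model inputs for one strategy arm."""

    transitions: dict[tuple[str, str], float]
    utilities: dict[str, float]  # state -> utility, death excluded (0)
    costs: dict[str, float]  # state -> annual USD, death excluded (0)
    mortality: MortalityTable
    arm: ArmParameters
    economics: EconomicSettings = field(default_factory=EconomicSettings)
    #: symbol -> (low, high, distribution) ranges for sensitivity analyses
    sensitivity: dict[str, tuple[float, float, str]] = field(default_factory=dict)

    def __post_init__(self):
        for (o, d), p in self.transitions.items():
            if o not in STATES or d not in STATES:
                raise ParameterError(f"unknown state in transition {(o, d)}")
            if o == DEATH:
                raise ParameterError("death is absorbing; no outgoing transitions")
            if not 0.0 <= p <= 1.0:
                raise ParameterError(f"transition {(o, d)} probability {p} outside [0, 1]")
        for s, u in self.utilities.items():
            if not 0.0 <= u <= 1.0:
                raise ParameterError(f"utility of {s} outside [0, 1]")
        for s, c in self.costs.items():
            if c < 0:
                raise ParameterError(f"cost of {s} negative")
        missing_u = [s for s in STATES if s != DEATH and s not in self.utilities]
        if missing_u:
            raise ParameterError(f"missing utilities for states: {missing_u}")
        missing_c = [s for s in STATES if s != DEATH and s not in self.costs]
        if missing_c:
            raise ParameterError(f"missing costs for states: {missing_c}")

    def copy(self) -> "ParameterSet":
        return copy.deepcopy(self)

    def transition(self, origin: str, destination: str) -> float:
        return self.transitions.get((origin, destination), 0.0)

    # -- named-parameter access (table symbols) ---------------------------
    def set_value(self, name: str, value: float) -> None:
        """Set a parameter in place by its table symbol.

        Recognizes transition symbols (p0.5_1 ...), utilities (U_*),
        state costs (cprehy ...), arm fields (control_rate, human_cost,
        project_cost and their table aliases resolved upstream), and the
        economics fields discount_rate and wtp.
        """
        if name in UTILITY_SYMBOLS:
            self.utilities[UTILITY_SYMBOLS[name]] = value
            return
        if name in COST_SYMBOLS:
            self.costs[COST_SYMBOLS[name]] = value
            return
        if name == "discount_rate":
            self.economics = replace(self.economics, discount_rate=value)
            return
        if name == "wtp":
            self.economics = replace(self.economics, wtp=value)
            return
        if name == "control_rate":
            self.arm.control_rate = value
            return
        if name == "human_cost":
            self.arm.human_cost = value
            return
        if name == "project_cost":
            self.arm.project_cost = value
            return
        try:
            pair = parse_transition_symbol(name)
        except ValueError:
            raise ParameterError(f"unknown parameter name {name!r}") from None
        self.transitions[pair] = value

    def with_value(self, name: str, value: float) -> "ParameterSet":
        ps = self.copy()
        ps.set_value(name, value)
        return ps
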