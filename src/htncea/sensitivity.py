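"""One-way (tornado) and probabilistic sensitivity analysis.

One-way analysis re-runs the full multi-arm model with a single
parameter pushed to the low and high end of its published range,
everything else held at base value, and tabulates the swing of a chosen
outcome (default: the ICER of option2 vs usual practice).

The probabilistic analysis is a second-order Monte Carlo simulation:
each iteration draws every uncertain parameter once from its assigned
distribution (beta for probabilities, utilities and control rates;
gamma for costs), rebuilds all arms with the shared draw and records
the discounted totals.  Distribution hyperparameters come from moment
matching with SD = (CI width) / 3.92, i.e. the published range is read
as a 95% interval.  Draws are independent across parameters.  The
cost-effectiveness acceptability curve (CEAC) reports, over a grid of
willingness-to-pay values, the fraction of iterations in which each arm
has the highest net monetary benefit (ties split equally).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .cea import icer
from .model import run_cohort, Totals
from .params import ParameterSet

#: table symbols whose value lives on one specific arm
ARM_SCOPED = {
    "PSCR": ("usual", "control_rate"),
    "SSCR": ("option1", "control_rate"),
    "DSCR": ("option2", "control_rate"),
    "cphuman": ("usual", "human_cost"),
    "cshuman": ("option1", "human_cost"),
    "cdhuman": ("option2", "human_cost"),
    "cpprogram": ("usual", "project_cost"),
    "csprogram": ("option1", "project_cost"),
    "cdproagram": ("option2", "project_cost"),
}


class SensitivityError(ValueError):
    pass


@dataclass(frozen=True)
class ParameterSpec:
    """One uncertain parameter: base value, range, distribution family."""

    name: str
    base: float
    low: float
    high: float
    distribution: str = "fixed"  # beta | gamma | fixed
    arm: str | None = None  # None: shared across arms

    def __post_init__(self):
        if not self.low <= self.base <= self.high:
            raise SensitivityError(
                f"{self.name}: require low <= base <= high, "
                f"got ({self.low}, {self.base}, {self.high})"
            )
        if self.distribution == "beta" and not (0 <= self.low and self.high <= 1):
            raise SensitivityError(f"{self.name}: beta requires values in [0, 1]")
        if self.distribution == "gamma" and self.low < 0:
            raise SensitivityError(f"{self.name}: gamma requires non-negative values")
        if self.distribution not in ("beta", "gamma", "fixed"):
            raise SensitivityError(f"{self.name}: unknown distribution")

    @property
    def degenerate(self) -> bool:
        return self.distribution == "fixed" or self.high == self.low


@dataclass
class TornadoRow:
    parameter: str
    outcome_low: float
    outcome_high: float

    @property
    def swing(self) -> float:
        return abs(self.outcome_high - self.outcome_low)


# --- distribution fitting -------------------------------------------------

def beta_from_mean_ci(mean: float, low: float, high: float) -> tuple[float, float]:
    """Beta (alpha, beta) by moment matching, SD = (high-low)/3.92."""
    if not 0 < mean < 1:
        raise SensitivityError("beta mean must lie strictly in (0, 1)")
    if low >= high:
        raise SensitivityError("need low < high for a beta fit")
    sd = (high - low) / 3.92
    var = sd * sd
    if var >= mean * (1 - mean):
        raise SensitivityError(
            f"CI ({low}, {high}) implies variance {var:.4g} incompatible "
            f"with a beta of mean {mean}"
        )
    nu = mean * (1 - mean) / var - 1
    return mean * nu, (1 - mean) * nu


def gamma_from_mean_ci(mean: float, low: float, high: float) -> tuple[float, float]:
    """Gamma (shape, scale) by moment matching, SD = (high-low)/3.92."""
    if mean <= 0:
        raise SensitivityError("gamma mean must be positive")
    if low >= high:
        raise SensitivityError("need low < high for a gamma fit")
    sd = (high - low) / 3.92
    return (mean / sd) ** 2, sd * sd / mean


# --- parameter plumbing ---------------------------------------------------

def default_parameter_specs(arms: Mapping[str, ParameterSet]) -> list[ParameterSpec]:
    """Specs built from the sensitivity sections of the arm files.

    Shared parameters (transitions, utilities, state costs, discount
    rate) are emitted once; control rates and intervention costs once
    per arm under their table aliases (PSCR/SSCR/DSCR, cphuman, ...).
    """
    specs: dict[str, ParameterSpec] = {}
    alias_by_field = {
        ("usual", "control_rate"): "PSCR", ("option1", "control_rate"): "SSCR",
        ("option2", "control_rate"): "DSCR",
        ("usual", "human_cost"): "cphuman", ("option1", "human_cost"): "cshuman",
        ("option2", "human_cost"): "cdhuman",
        ("usual", "project_cost"): "cpprogram", ("option1", "project_cost"): "csprogram",
        ("option2", "project_cost"): "cdproagram",
    }
    for arm_name, ps in arms.items():
        for name, (lo, hi, dist) in ps.sensitivity.items():
            if name in ("control_rate", "human_cost", "project_cost"):
                alias = alias_by_field.get((arm_name, name), f"{arm_name}:{name}")
                base = getattr(ps.arm, name)
                specs[alias] = ParameterSpec(alias, base, lo, hi, dist, arm=arm_name)
            elif name not in specs:
                if name == "discount_rate":
                    base = ps.economics.discount_rate
                elif name == "wtp":
                    base = ps.economics.wtp
                else:
                    base = _lookup_symbol(ps, name)
                specs[name] = ParameterSpec(name, base, lo, hi, dist)
    return list(specs.values())


def _lookup_symbol(ps: ParameterSet, name: str) -> float:
    from .params import COST_SYMBOLS, UTILITY_SYMBOLS
    from .states import parse_transition_symbol

    if name in UTILITY_SYMBOLS:
        return ps.utilities[UTILITY_SYMBOLS[name]]
    if name in COST_SYMBOLS:
        return ps.costs[COST_SYMBOLS[name]]
    return ps.transition(*parse_transition_symbol(name))


def apply_values(
    arms: Mapping[str, ParameterSet], values: Mapping[str, float]
) -> dict[str, ParameterSet]:
    """Fresh arm ParameterSets with the named parameters replaced.

    Arm-scoped names (PSCR, cshuman, ... or ``arm:field``) touch only
    their arm; every other symbol is set on all arms.
    """
    out = {name: ps.copy() for name, ps in arms.items()}
    for name, value in values.items():
        if name in ARM_SCOPED:
            arm_name, fld = ARM_SCOPED[name]
            if arm_name in out:
                out[arm_name].set_value(fld, value)
        elif ":" in name:
            arm_name, fld = name.split(":", 1)
            out[arm_name].set_value(fld, value)
        else:
            for ps in out.values():
                ps.set_value(name, value)
    return out


def run_arms(arms: Mapping[str, ParameterSet]) -> dict[str, Totals]:
    return {name: run_cohort(ps).totals for name, ps in arms.items()}


def icer_outcome(intervention: str = "option2", comparator: str = "usual"):
    """Outcome functional: ICER of one pair from per-arm totals."""

    def outcome(totals: Mapping[str, Totals]) -> float:
        dc = totals[intervention].cost - totals[comparator].cost
        de = totals[intervention].qaly - totals[comparator].qaly
        return icer(dc, de).ratio

    return outcome


# --- one-way analysis -----------------------------------------------------

def one_way_analysis(
    arms: Mapping[str, ParameterSet],
    specs: Sequence[ParameterSpec],
    outcome: Callable[[Mapping[str, Totals]], float] | None = None,
) -> pd.DataFrame:
    """Tornado table: outcome at each parameter's low and high bound.

    Returns a DataFrame (parameter, outcome_low, outcome_high, swing)
    sorted by decreasing swing.
    """
    outcome = outcome or icer_outcome()
    rows = []
    for spec in specs:
        lo = outcome(run_arms(apply_values(arms, {spec.name: spec.low})))
        hi = outcome(run_arms(apply_values(arms, {spec.name: spec.high})))
        rows.append(TornadoRow(spec.name, lo, hi))
    rows.sort(key=lambda r: r.swing, reverse=True)
    return pd.DataFrame(
        {
            "parameter": [r.parameter for r in rows],
            "outcome_low": [r.outcome_low for r in rows],
            "outcome_high": [r.outcome_high for r in rows],
            "swing": [r.swing for r in rows],
        }
    )


# --- probabilistic analysis ----------------------------------------------

@dataclass
class PSAResult:
    """Per-iteration totals and the acceptability curve."""

    samples: pd.DataFrame  # iteration, arm, cost, ly, qaly
    ceac: pd.DataFrame  # wtp + one probability column per arm
    draws: pd.DataFrame = field(repr=False, default=None)

    def cost_effectiveness_probability(self, wtp: float) -> dict[str, float]:
        """Per-arm probability of highest NMB at one WTP value."""
        row = self.ceac.iloc[(self.ceac["wtp"] - wtp).abs().argmin()]
        return {c: float(row[c]) for c in self.ceac.columns if c != "wtp"}


def _sample_spec(spec: ParameterSpec, n: int, rng: np.random.Generator) -> np.ndarray:
    if spec.degenerate:
        return np.full(n, spec.base)
    if spec.distribution == "beta":
        a, b = beta_from_mean_ci(spec.base, spec.low, spec.high)
        return rng.beta(a, b, size=n)
    if spec.distribution == "gamma":
        shape, scale = gamma_from_mean_ci(spec.base, spec.low, spec.high)
        return rng.gamma(shape, scale, size=n)
    return np.full(n, spec.base)


def ceac_from_samples(
    samples: pd.DataFrame, wtp_grid: np.ndarray
) -> pd.DataFrame:
    """Fraction of iterations each arm wins (highest NMB) per WTP."""
    wide_c = samples.pivot(index="iteration", columns="arm", values="cost")
    wide_e = samples.pivot(index="iteration", columns="arm", values="qaly")
    arms = list(wide_c.columns)
    out = []
    for wtp in wtp_grid:
        nmb = wtp * wide_e.to_numpy() - wide_c.to_numpy()
        best = nmb.max(axis=1, keepdims=True)
        winners = nmb >= best - 1e-12  # ties split equally
        probs = (winners / winners.sum(axis=1, keepdims=True)).mean(axis=0)
        out.append({"wtp": float(wtp), **dict(zip(arms, probs))})
    return pd.DataFrame(out)


def default_wtp_grid(wtp: float = 1599.16, n: int = 100) -> np.ndarray:
    """0 to 4x the base WTP, always containing the base WTP exactly."""
    grid = np.linspace(0.0, 4.0 * wtp, n + 1)
    return np.unique(np.append(grid, wtp))


def run_psa(
    arms: Mapping[str, ParameterSet],
    specs: Sequence[ParameterSpec],
    n_iter: int = 1000,
    seed: int = 0,
    wtp_grid: np.ndarray | None = None,
) -> PSAResult:
    """Second-order Monte Carlo over the parameter distributions."""
    if n_iter < 1:
        raise SensitivityError("n_iter must be at least 1")
    rng = np.random.default_rng(seed)
    if wtp_grid is None:
        wtp = next(iter(arms.values())).economics.wtp
        wtp_grid = default_wtp_grid(wtp)
    draws = pd.DataFrame({s.name: _sample_spec(s, n_iter, rng) for s in specs})
    records = []
    for it in range(n_iter):
        drawn = apply_values(arms, draws.iloc[it].to_dict()) if specs else dict(arms)
        for name, ps in drawn.items():
            t = run_cohort(ps).totals
            records.append(
                dict(iteration=it, arm=name, cost=t.cost, ly=t.ly, qaly=t.qaly)
            )
    samples = pd.DataFrame(records)
    return PSAResult(samples=samples, ceac=ceac_from_samples(samples, wtp_grid),
                     draws=draws)
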