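"""Reading and writing parameter files, follow-up records and reports.

Parameter files are YAML with six sections -- arm, transitions,
utilities, costs, mortality, economics -- plus an optional sensitivity
section of {low, high, distribution} ranges.  All names mirror the
source-table symbols (p0.5_1, U_MI, chy2, ...).  Packaged files
transcribe the published tables for the three strategy arms
(``usual``, ``option1``, ``option2``).
"""

from __future__ import annotations

import importlib.resources
from pathlib import Path

import pandas as pd
import yaml

from .estimation import RECORD_COLUMNS, TransitionCountTable, validate_records
from .params import (
    ArmParameters,
    EconomicSettings,
    MortalityTable,
    ParameterError,
    ParameterSet,
    COST_SYMBOLS,
    UTILITY_SYMBOLS,
)
from .states import parse_transition_symbol

ARM_NAMES = ("usual", "option1", "option2")

_SECTIONS = ("arm", "transitions", "utilities", "costs", "mortality", "economics")
_ARM_KEYS = {
    "label", "control_rate", "human_cost", "project_cost",
    "n_enrolled", "intervention_span_years", "lifelong_programme",
    "intervention_cycles",
}
_ECON_KEYS = {
    "discount_rate", "discount_rate_range", "wtp", "horizon", "cycle_length",
    "start_age", "initial_distribution", "reference_control_rate",
}
_UTILITY_BY_STATE = {v: k for k, v in UTILITY_SYMBOLS.items()}
_COST_BY_STATE = {v: k for k, v in COST_SYMBOLS.items()}


class ParameterFileError(ParameterError):
    """Malformed parameter file; the message names the offending key."""


def _check_keys(mapping: dict, allowed: set, where: str, required: set | None = None):
    unknown = set(mapping) - allowed
    if unknown:
        raise ParameterFileError(f"unknown keys in {where}: {sorted(unknown)}")
    if required:
        missing = required - set(mapping)
        if missing:
            raise ParameterFileError(f"missing keys in {where}: {sorted(missing)}")


def parameter_set_from_dict(doc: dict, source: str = "<dict>") -> ParameterSet:
    _check_keys(doc, set(_SECTIONS) | {"sensitivity"}, source, set(_SECTIONS))

    arm_doc = dict(doc["arm"])
    _check_keys(arm_doc, _ARM_KEYS, f"{source}:arm", {"label", "control_rate"})
    arm = ArmParameters(**arm_doc)

    transitions = {}
    for symbol, value in doc["transitions"].items():
        try:
            pair = parse_transition_symbol(str(symbol))
        except ValueError as exc:
            raise ParameterFileError(f"{source}:transitions: {exc}") from None
        transitions[pair] = float(value)

    utilities = {}
    for symbol, value in doc["utilities"].items():
        if symbol not in UTILITY_SYMBOLS:
            raise ParameterFileError(f"{source}:utilities: unknown symbol {symbol!r}")
        utilities[UTILITY_SYMBOLS[symbol]] = float(value)
    missing = set(UTILITY_SYMBOLS) - set(doc["utilities"])
    if missing:
        raise ParameterFileError(f"{source}:utilities: missing {sorted(missing)}")

    costs = {}
    for symbol, value in doc["costs"].items():
        if symbol not in COST_SYMBOLS:
            raise ParameterFileError(f"{source}:costs: unknown symbol {symbol!r}")
        costs[COST_SYMBOLS[symbol]] = float(value)
    missing = set(COST_SYMBOLS) - set(doc["costs"])
    if missing:
        raise ParameterFileError(f"{source}:costs: missing {sorted(missing)}")

    mortality = MortalityTable({int(a): float(q) for a, q in doc["mortality"].items()})

    econ_doc = dict(doc["economics"])
    _check_keys(econ_doc, _ECON_KEYS, f"{source}:economics")
    econ_doc.pop("discount_rate_range", None)
    economics = EconomicSettings(**econ_doc)

    sensitivity = {}
    for name, rng in (doc.get("sensitivity") or {}).items():
        _check_keys(dict(rng), {"low", "high", "distribution"},
                    f"{source}:sensitivity:{name}", {"low", "high", "distribution"})
        sensitivity[str(name)] = (float(rng["low"]), float(rng["high"]),
                                  str(rng["distribution"]))

    return ParameterSet(
        transitions=transitions, utilities=utilities, costs=costs,
        mortality=mortality, arm=arm, economics=economics, sensitivity=sensitivity,
    )


def parameter_set_to_dict(ps: ParameterSet) -> dict:
    from .states import transition_symbol

    econ = ps.economics
    doc = {
        "arm": {
            "label": ps.arm.label,
            "control_rate": ps.arm.control_rate,
            "human_cost": ps.arm.human_cost,
            "project_cost": ps.arm.project_cost,
            "n_enrolled": ps.arm.n_enrolled,
            "intervention_span_years": ps.arm.intervention_span_years,
            "lifelong_programme": ps.arm.lifelong_programme,
        },
        "transitions": {
            transition_symbol(o, d): p for (o, d), p in sorted(ps.transitions.items())
        },
        "utilities": {_UTILITY_BY_STATE[s]: u for s, u in ps.utilities.items()},
        "costs": {_COST_BY_STATE[s]: c for s, c in ps.costs.items()},
        "mortality": dict(sorted(ps.mortality.bands.items())),
        "economics": {
            "discount_rate": econ.discount_rate,
            "wtp": econ.wtp,
            "horizon": econ.horizon,
            "cycle_length": econ.cycle_length,
            "start_age": econ.start_age,
            "initial_distribution": dict(econ.initial_distribution),
            "reference_control_rate": econ.reference_control_rate,
        },
    }
    if ps.sensitivity:
        doc["sensitivity"] = {
            name: {"low": lo, "high": hi, "distribution": dist}
            for name, (lo, hi, dist) in ps.sensitivity.items()
        }
    return doc


def load_parameter_set(path: str | Path) -> ParameterSet:
    """Read and validate a YAML parameter file."""
    path = Path(path)
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise ParameterFileError(f"{path}: not a mapping")
    return parameter_set_from_dict(doc, source=str(path))


def save_parameter_set(ps: ParameterSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(parameter_set_to_dict(ps), fh, sort_keys=False)


def load_packaged_arm(name: str) -> ParameterSet:
    """Packaged table transcription for one arm (usual/option1/option2)."""
    if name not in ARM_NAMES:
        raise ParameterFileError(f"unknown arm {name!r}; choose from {ARM_NAMES}")
    ref = importlib.resources.files("htncea.data").joinpath(f"{name}.yaml")
    doc = yaml.safe_load(ref.read_text())
    return parameter_set_from_dict(doc, source=f"packaged:{name}")


def load_packaged_arms() -> dict[str, ParameterSet]:
    return {name: load_packaged_arm(name) for name in ARM_NAMES}


def load_packaged_study_counts() -> TransitionCountTable:
    """Observed baseline-to-final transition counts of the source trial."""
    ref = importlib.resources.files("htncea.data").joinpath("study_counts.csv")
    with importlib.resources.as_file(ref) as path:
        df = pd.read_csv(path)
    counts = {
        (row.origin, row.destination): int(row.count_)
        for row in df.rename(columns={"count": "count_"}).itertuples()
    }
    return TransitionCountTable(counts=counts, total_n=int(sum(counts.values())))


# --- follow-up records ----------------------------------------------------

def load_follow_up_records(path: str | Path, validate: bool = True) -> pd.DataFrame:
    df = pd.read_csv(path)
    if validate:
        validate_records(df)
    return df


def save_follow_up_records(records: pd.DataFrame, path: str | Path) -> None:
    records.to_csv(path, index=False, columns=list(RECORD_COLUMNS))
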