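"""Health-state space of the hypertension progression model.

The cohort model distinguishes nine states: four blood-pressure levels
(prehypertension and hypertension grades 1-3, defined by the standard
SBP/DBP cutpoints), four complication states (myocardial infarction,
stroke, congestive heart failure, end-stage renal disease) and absorbing
death.  Normotension can occur in follow-up *records* but is not a model
state: managed hypertensive patients are assumed not to return to
normotension, prehypertension being the best attainable state.
"""

from __future__ import annotations

PREHYPERTENSION = "prehypertension"
L1 = "L1"
L2 = "L2"
L3 = "L3"
MI = "MI"
STROKE = "stroke"
CHF = "CHF"
ESRD = "ESRD"
DEATH = "death"

#: canonical state order used by every matrix and trace
STATES: tuple[str, ...] = (PREHYPERTENSION, L1, L2, L3, MI, STROKE, CHF, ESRD, DEATH)
HYPERTENSION_STATES: tuple[str, ...] = (PREHYPERTENSION, L1, L2, L3)
COMPLICATION_STATES: tuple[str, ...] = (MI, STROKE, CHF, ESRD)
ABSORBING: tuple[str, ...] = (DEATH,)

#: recorded in longitudinal data only, never a model state
NORMOTENSION = "normotension"
RECORD_STATES: tuple[str, ...] = (NORMOTENSION,) + HYPERTENSION_STATES

STATE_INDEX = {s: i for i, s in enumerate(STATES)}
N_STATES = len(STATES)

#: blood-pressure severity rank (used to detect "improvement" transitions)
SEVERITY = {PREHYPERTENSION: 0, L1: 1, L2: 2, L3: 3}

#: (sbp_low, sbp_high, dbp_low, dbp_high) bands per recorded state.
#: L3 is open-ended upward; the upper numbers are emission caps for the
#: synthetic generator, not clinical limits.
BP_BANDS = {
    NORMOTENSION: (90.0, 119.9, 60.0, 79.9),
    PREHYPERTENSION: (120.0, 139.9, 80.0, 89.9),
    L1: (140.0, 159.9, 90.0, 99.9),
    L2: (160.0, 179.9, 100.0, 109.9),
    L3: (180.0, 210.0, 110.0, 130.0),
}


def is_improvement(origin: str, destination: str) -> bool:
    """True for a move to a strictly less severe blood-pressure level."""
    return (
        origin in SEVERITY
        and destination in SEVERITY
        and SEVERITY[destination] < SEVERITY[origin]
    )


# --- parameter-symbol handling -------------------------------------------
# Transition parameters are named after the source tables: p0.5_1 is
# prehypertension -> hypertension-L1, pESRD_Death is ESRD -> death, etc.
# Case of the leading "p" and of the tokens varies in print; parsing is
# case-insensitive, writing uses the printed form.

_TOKEN_TO_STATE = {
    "0.5": PREHYPERTENSION,
    "1": L1,
    "2": L2,
    "3": L3,
    "mi": MI,
    "stroke": STROKE,
    "chf": CHF,
    "esrd": ESRD,
    "death": DEATH,
}
_STATE_TO_TOKEN = {
    PREHYPERTENSION: "0.5",
    L1: "1",
    L2: "2",
    L3: "3",
    MI: "MI",
    STROKE: "Stroke",
    CHF: "CHF",
    ESRD: "ESRD",
    DEATH: "Death",
}


def parse_transition_symbol(symbol: str) -> tuple[str, str]:
    """Decode a table-style transition name into (origin, destination).

    >>> parse_transition_symbol("p0.5_1")
    ('prehypertension', 'L1')
    """
    body = symbol[1:] if symbol[:1] in ("p", "P") else symbol
    try:
        left, right = body.split("_")
        return _TOKEN_TO_STATE[left.lower()], _TOKEN_TO_STATE[right.lower()]
    except (ValueError, KeyError):
        raise ValueError(f"unrecognized transition symbol: {symbol!r}") from None


def transition_symbol(origin: str, destination: str) -> str:
    """Encode (origin, destination) in the printed table naming."""
    return f"p{_STATE_TO_TOKEN[origin]}_{_STATE_TO_TOKEN[destination]}"
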