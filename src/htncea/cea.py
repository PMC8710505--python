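"""Incremental cost-utility comparison of strategies.

Implements the standard decision statistics at a willingness-to-pay
(WTP) threshold lambda:

* ICER = dC / dE (USD per QALY),
* net monetary benefit  NMB = lambda * dE - dC (USD),
* net health benefit    NHB = dE - dC / lambda (QALYs),

with dominance classification: an arm that is cheaper and more
effective than its comparator dominates it.  Negative ICERs are
reported alongside the dominance flag rather than suppressed, matching
how such results are usually tabulated.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

DOMINANT = "dominant"
DOMINATED = "dominated"
WELL_DEFINED = "well_defined"
UNDEFINED = "undefined"


class CEAError(ValueError):
    pass


@dataclass(frozen=True)
class ICERValue:
    """Ratio plus qualitative flag; ``ratio`` is NaN when dE = 0."""

    ratio: float
    flag: str


@dataclass(frozen=True)
class CEAResult:
    intervention: str
    comparator: str
    delta_cost: float
    delta_qaly: float
    icer: ICERValue
    nmb: float
    nhb: float
    verdict: str


def icer(delta_cost: float, delta_qaly: float) -> ICERValue:
    """Incremental cost-effectiveness ratio with dominance flag."""
    if delta_qaly == 0:
        return ICERValue(ratio=float("nan"), flag=UNDEFINED)
    flag = WELL_DEFINED
    if delta_cost < 0 and delta_qaly > 0:
        flag = DOMINANT
    elif delta_cost > 0 and delta_qaly < 0:
        flag = DOMINATED
    return ICERValue(ratio=delta_cost / delta_qaly, flag=flag)


def nmb(delta_cost: float, delta_qaly: float, wtp: float) -> float:
    """Net monetary benefit WTP*dE - dC."""
    if wtp <= 0:
        raise CEAError("willingness to pay must be positive")
    return wtp * delta_qaly - delta_cost


def nhb(delta_cost: float, delta_qaly: float, wtp: float) -> float:
    """Net health benefit dE - dC/WTP."""
    if wtp <= 0:
        raise CEAError("willingness to pay must be positive")
    return delta_qaly - delta_cost / wtp


def compare_pair(
    intervention: str,
    comparator: str,
    totals: Mapping[str, tuple],
    wtp: float,
) -> CEAResult:
    ci, ei = totals[intervention][0], totals[intervention][-1]
    cc, ec = totals[comparator][0], totals[comparator][-1]
    dc, de = ci - cc, ei - ec
    r = icer(dc, de)
    if r.flag == DOMINANT:
        verdict = DOMINANT
    elif r.flag == DOMINATED:
        verdict = DOMINATED
    else:
        verdict = (
            "cost_effective_at_wtp" if nmb(dc, de, wtp) > 0 else "not_cost_effective_at_wtp"
        )
    return CEAResult(
        intervention=intervention, comparator=comparator,
        delta_cost=dc, delta_qaly=de, icer=r,
        nmb=nmb(dc, de, wtp), nhb=nhb(dc, de, wtp), verdict=verdict,
    )


def compare_strategies(
    totals: Mapping[str, tuple],
    wtp: float,
    pairs: Sequence[tuple[str, str]] | None = None,
) -> list[CEAResult]:
    """All pairwise incremental comparisons.

    ``totals`` maps arm label -> (cost, ..., qaly); a :class:`Totals`
    namedtuple works directly.  By default every ordered pair in which
    the intervention is the later label is compared, except that the
    conventional three-arm order (option1 vs usual, option2 vs usual,
    option2 vs option1) is used when those labels are present.
    """
    labels = list(totals)
    if len(labels) != len(set(labels)):
        raise CEAError("duplicate arm labels")
    if len(labels) < 2:
        raise CEAError("need at least two arms to compare")
    if pairs is None:
        if set(labels) >= {"option1", "option2", "usual"}:
            pairs = [("option1", "usual"), ("option2", "usual"), ("option2", "option1")]
        else:
            pairs = [
                (b, a) for i, a in enumerate(labels) for b in labels[i + 1:]
            ]
    return [compare_pair(i, c, totals, wtp) for i, c in pairs]


def efficiency_frontier(totals: Mapping[str, tuple]) -> list[str]:
    """Arms on the cost-effectiveness frontier, by increasing cost.

    Strictly dominated arms (another arm no more costly and no less
    effective, better on at least one) are removed.
    """
    arms = [(label, t[0], t[-1]) for label, t in totals.items()]
    frontier = []
    for label, c, e in sorted(arms, key=lambda x: (x[1], -x[2])):
        dominated = any(
            (c2 <= c and e2 >= e) and (c2 < c or e2 > e) for _, c2, e2 in arms
        )
        if not dominated:
            frontier.append(label)
    return frontier


def results_table(results: Sequence[CEAResult]) -> pd.DataFrame:
    """Report rows rounded to cents and 0.001 QALYs."""
    return pd.DataFrame(
        {
            "comparison": [f"{r.intervention} vs {r.comparator}" for r in results],
            "delta_cost": [round(r.delta_cost, 2) for r in results],
            "delta_qaly": [round(r.delta_qaly, 3) for r in results],
            "icer": [round(r.icer.ratio, 2) for r in results],
            "icer_flag": [r.icer.flag for r in results],
            "nmb": [round(r.nmb, 2) for r in results],
            "nhb": [round(r.nhb, 3) for r in results],
            "verdict": [r.verdict for r in results],
        }
    )
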