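"""Convenience plots for sensitivity-analysis outputs (tornado, CEAC).

Thin matplotlib wrappers around the tabular results; the tables are the
primary artifacts, styling here is minimal.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd


def plot_tornado(tornado: pd.DataFrame, base_outcome: float, path: str) -> None:
    """Horizontal bar chart of one-way swings around the base outcome."""
    df = tornado.sort_values("swing")
    fig, ax = plt.subplots(figsize=(7, 0.35 * len(df) + 1.5))
    for i, row in enumerate(df.itertuples()):
        lo, hi = sorted([row.outcome_low, row.outcome_high])
        ax.barh(i, hi - lo, left=lo, color="steelblue", height=0.6)
    ax.axvline(base_outcome, color="black", lw=1)
    ax.set_yticks(range(len(df)), df["parameter"])
    ax.set_xlabel("outcome at parameter bounds")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_ceac(ceac: pd.DataFrame, path: str) -> None:
    """Cost-effectiveness acceptability curves, one line per arm."""
    fig, ax = plt.subplots(figsize=(7, 4.5))
    for arm in [c for c in ceac.columns if c != "wtp"]:
        ax.plot(ceac["wtp"], ceac[arm], label=arm)
    ax.set_xlabel("willingness to pay (USD/QALY)")
    ax.set_ylabel("probability cost-effective")
    ax.set_ylim(0, 1)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
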