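"""Minimal plotting helpers (bar chart of fold changes, Cq spread boxes)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt

from .datamodel import CqTable
from .expression import ExpressionResult

__all__ = ["plot_expression", "plot_cq_spread"]


def plot_expression(result: ExpressionResult, gene: str, ax=None):
    """Bar chart of per-condition fold changes with SEM bars and letters."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 3.5))
    sub = result.summary.loc[gene]
    conds = [c for c in result.conditions if c in sub.index]
    fc = [sub.loc[c, "fold_change"] for c in conds]
    sem = [sub.loc[c, "sem"] for c in conds]
    letters = [sub.loc[c, "letters"] for c in conds]
    bars = ax.bar(range(len(conds)), fc, yerr=sem, capsize=3, color="0.3")
    for x, (bar, letter, s) in enumerate(zip(bars, letters, sem)):
        ax.text(x, bar.get_height() + s + 0.05 * max(fc), letter,
                ha="center", va="bottom", fontsize=9)
    ax.set_xticks(range(len(conds)))
    ax.set_xticklabels(conds, rotation=45, ha="right", fontsize=8)
    ax.set_ylabel("fold change (2^-ddCt)")
    ax.set_title(gene)
    return ax


def plot_cq_spread(table: CqTable, ax=None):
    """Box plot of raw Cq values per gene (replicates of all conditions)."""
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 3.5))
    data = [table.values.loc[g].dropna().to_numpy() for g in table.genes]
    ax.boxplot(data, tick_labels=table.genes, whis=1.5)
    ax.set_ylabel("Cq (cycles)")
    ax.tick_params(axis="x", rotation=45, labelsize=8)
    return ax
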