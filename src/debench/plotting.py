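"""Minimal benchmark plots: eFDR / call-count violins and MA scatters."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from debench.orchestration import STAGES  # noqa: E402

__all__ = ["efdr_violin", "intra_count_violin", "ma_plot"]


def _violin_by_stage(df: pd.DataFrame, value: str, ylabel: str, path: Path) -> None:
    callers = df["caller"].unique()
    fig, axes = plt.subplots(1, len(callers), figsize=(4 * len(callers), 3.2),
                             sharey=True, squeeze=False)
    for ax, caller in zip(axes[0], callers):
        data, labels = [], []
        for stage in STAGES:
            vals = df.query("caller == @caller and stage == @stage")[value].dropna()
            if len(vals):
                data.append(vals.to_numpy())
                labels.append(stage)
        if data:
            ax.violinplot(data, showmedians=True)
            ax.set_xticks(range(1, len(labels) + 1), labels, rotation=30)
        ax.set_title(caller)
        ax.set_ylabel(ylabel)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def efdr_violin(comparisons: pd.DataFrame, path: str | Path) -> None:
    """Per-stage violins of site-pair empirical FDR, one panel per caller."""
    _violin_by_stage(comparisons, "efdr", "eFDR", Path(path))


def intra_count_violin(intra_counts: pd.DataFrame, path: str | Path) -> None:
    """Per-stage violins of intra-site DE call counts."""
    _violin_by_stage(intra_counts, "n_calls", "DE calls", Path(path))


def ma_plot(ma_table: pd.DataFrame, called: set[str], path: str | Path, title: str = "") -> None:
    """MA scatter with called genes highlighted."""
    fig, ax = plt.subplots(figsize=(4.5, 3.5))
    is_called = ma_table["gene_id"].isin(called)
    ax.scatter(ma_table.loc[~is_called, "a_value"], ma_table.loc[~is_called, "m_value"],
               s=2, c="0.7", linewidths=0)
    ax.scatter(ma_table.loc[is_called, "a_value"], ma_table.loc[is_called, "m_value"],
               s=3, c="crimson", linewidths=0)
    ax.axhline(0.0, lw=0.5, c="k")
    ax.set_xlabel("A (average log2 expression)")
    ax.set_ylabel("M (log2 fold change)")
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
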