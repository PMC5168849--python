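"""Post-hoc call filters: significance, effect strength, average expression.

Calls require q < q_max (strict) and |log2FC| > min_abs_log2fc (strict).  The
optional average-expression (AE) filter removes the weakest genes below a
percentile of the table's own A-value distribution; the percentile is
calibrated so that an average (median) site yields a target number of
intra-site DE calls, equalizing sensitivity across pipelines before
specificity and reproducibility are compared.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = ["FilterSpec", "CallSet", "apply_filters", "calibrate_ae_threshold", "CalibrationResult"]


@dataclass(frozen=True)
class FilterSpec:
    """Thresholds of the call-filter cascade.

    ``ae_percentile`` is the percentage of lowest-A genes excluded
    (``None`` disables the AE filter; 0 keeps every gene).
    """

    q_max: float = 0.05
    min_abs_log2fc: float = 1.0
    ae_percentile: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.q_max <= 1.0:
            raise ValueError("q_max must lie in [0, 1]")
        if self.min_abs_log2fc < 0:
            raise ValueError("min_abs_log2fc must be >= 0")
        if self.ae_percentile is not None and not 0.0 <= self.ae_percentile <= 100.0:
            raise ValueError("ae_percentile must lie in [0, 100]")


@dataclass
class CallSet:
    """A labelled set of DE calls with per-gene direction of change."""

    label: str
    genes: dict[str, str]  # gene_id -> "up" | "down"

    def __len__(self) -> int:
        return len(self.genes)


def _pass_mask(table: pd.DataFrame, spec: FilterSpec) -> np.ndarray:
    q = table["qvalue"].to_numpy(dtype=float)
    lfc = np.abs(table["log2fc"].to_numpy(dtype=float))
    mask = q < spec.q_max
    if spec.min_abs_log2fc > 0:  # 0 disables the effect-strength filter
        mask &= lfc > spec.min_abs_log2fc
    if spec.ae_percentile is not None and spec.ae_percentile > 0:
        thr = np.percentile(table["ave_expr"].to_numpy(dtype=float), spec.ae_percentile)
        mask &= table["ave_expr"].to_numpy(dtype=float) >= thr
    return mask


def apply_filters(table: pd.DataFrame, spec: FilterSpec, label: str = "") -> CallSet:
    """Filter a DE table to a call set (strict q and |log2FC| thresholds)."""
    mask = _pass_mask(table, spec)
    sub = table.loc[mask, ["gene_id", "direction"]]
    return CallSet(label=label, genes=dict(zip(sub["gene_id"], sub["direction"])))


@dataclass
class CalibrationResult:
    """Outcome of the AE-percentile calibration."""

    ae_percentile: float
    achieved_median: float
    target: int
    unreachable: bool = False
    per_table_counts: list[int] = field(default_factory=list)


def calibrate_ae_threshold(
    per_site_tables: Sequence[pd.DataFrame],
    target: int = 3000,
    q_max: float = 0.05,
    min_abs_log2fc: float = 1.0,
    grid_step: float = 0.1,
) -> CalibrationResult:
    """Choose the AE percentile whose median intra-site call count is closest
    to ``target``.

    Searches a ``grid_step``-percentile grid (0 to 100), breaking ties toward
    the lower percentile.  If even percentile 0 (no AE filtering) leaves the
    median below target, the target is unreachable: percentile 0 is returned
    with ``unreachable=True``.
    """
    if not per_site_tables:
        raise ValueError("need at least one per-site DE table")
    if target < 1:
        raise ValueError("target must be >= 1")
    base = FilterSpec(q_max=q_max, min_abs_log2fc=min_abs_log2fc, ae_percentile=None)
    grid = np.round(np.arange(0.0, 100.0 + grid_step / 2, grid_step), 10)

    # per table: counts of base-passing genes above each grid threshold
    counts = np.zeros((len(per_site_tables), grid.size))
    for t, table in enumerate(per_site_tables):
        mask = _pass_mask(table, base)
        ave_all = table["ave_expr"].to_numpy(dtype=float)
        thresholds = np.percentile(ave_all, grid)
        passing = np.sort(ave_all[mask])
        # AE rule is ave_expr >= threshold
        counts[t] = passing.size - np.searchsorted(passing, thresholds, side="left")
    medians = np.median(counts, axis=0)

    if medians[0] < target:
        return CalibrationResult(
            ae_percentile=0.0,
            achieved_median=float(medians[0]),
            target=target,
            unreachable=True,
            per_table_counts=counts[:, 0].astype(int).tolist(),
        )
    best = int(np.argmin(np.abs(medians - target)))  # argmin takes the lowest index on ties
    return CalibrationResult(
        ae_percentile=float(grid[best]),
        achieved_median=float(medians[best]),
        target=target,
        unreachable=False,
        per_table_counts=counts[:, best].astype(int).tolist(),
    )
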