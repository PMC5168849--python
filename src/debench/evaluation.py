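"""Benchmark statistics: empirical FDR, list agreement, top-N concordance,
truth-based error rates, and a two-way sensitivity ANOVA.

The empirical FDR exploits the study design: comparing nominally identical
samples across sites (A-vs-A, C-vs-C) can only produce false positives, so
for a site pair

    eFDR = (A1-vs-A2 + C1-vs-C2) / (A1-vs-C2 + A2-vs-C1)

where each term counts filtered DE calls for that cross-site comparison.
Agreement between call lists is direction-aware: genes called in opposite
directions stay in the union but are excluded from the intersection.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf

from debench.filters import CallSet, FilterSpec, apply_filters

__all__ = [
    "ComparisonCounts",
    "AgreementResult",
    "efdr",
    "agreement",
    "topn_agreement",
    "run_comparisons",
    "truth_metrics",
    "anova_sensitivity",
]


@dataclass
class ComparisonCounts:
    """Filtered DE-call counts of the four cross-site comparisons of a pair."""

    site_pair: tuple[str, str]
    a1_vs_a2: int
    c1_vs_c2: int
    a1_vs_c2: int
    a2_vs_c1: int

    def __post_init__(self) -> None:
        for name in ("a1_vs_a2", "c1_vs_c2", "a1_vs_c2", "a2_vs_c1"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class AgreementResult:
    """Direction-aware concordance of two call lists."""

    pair: str
    n_union: int
    n_consistent_intersection: int
    agreement: float
    n_top: int | None = None


def efdr(counts: ComparisonCounts) -> tuple[float, bool]:
    """Empirical FDR of a site pair; returns ``(value, defined)``.

    A zero denominator (no cross-site A-vs-C calls) leaves the ratio
    undefined: NaN with ``defined=False``, never a silent 0.
    """
    num = counts.a1_vs_a2 + counts.c1_vs_c2
    den = counts.a1_vs_c2 + counts.a2_vs_c1
    if den == 0:
        return float("nan"), False
    return num / den, True


def agreement(set1: CallSet, set2: CallSet) -> AgreementResult:
    """Intersection-over-union of two call lists, direction-aware.

    Direction-discordant genes remain in the union but not the intersection.
    Two empty lists agree perfectly (1.0).
    """
    union = set(set1.genes) | set(set2.genes)
    consistent = {g for g in set(set1.genes) & set(set2.genes) if set1.genes[g] == set2.genes[g]}
    value = 1.0 if not union else len(consistent) / len(union)
    return AgreementResult(
        pair=f"{set1.label}|{set2.label}",
        n_union=len(union),
        n_consistent_intersection=len(consistent),
        agreement=value,
    )


def _ranked_calls(table: pd.DataFrame, spec: FilterSpec) -> pd.DataFrame:
    """Filter, then rank by decreasing |log2FC| (ties: larger ave_expr,
    then lexicographic gene_id) — the effect-strength ordering."""
    calls = apply_filters(table, spec)
    sub = table[table["gene_id"].isin(calls.genes)].copy()
    sub["abs_lfc"] = sub["log2fc"].abs()
    sub = sub.sort_values(
        by=["abs_lfc", "ave_expr", "gene_id"], ascending=[False, False, True], kind="mergesort"
    )
    return sub[["gene_id", "direction"]]


def topn_agreement(
    table1: pd.DataFrame,
    table2: pd.DataFrame,
    spec: FilterSpec,
    n: int,
    spec2: FilterSpec | None = None,
) -> AgreementResult:
    """Concordance of the N top-ranked filtered calls, divided by N.

    Lists shorter than N are used in full but the denominator stays N, so
    short lists are penalized.  Direction-discordant genes do not count.
    """
    if n < 1:
        raise ValueError("N must be >= 1")
    top1 = _ranked_calls(table1, spec).head(n)
    top2 = _ranked_calls(table2, spec2 or spec).head(n)
    d1 = dict(zip(top1["gene_id"], top1["direction"]))
    d2 = dict(zip(top2["gene_id"], top2["direction"]))
    consistent = {g for g in set(d1) & set(d2) if d1[g] == d2[g]}
    return AgreementResult(
        pair="topN",
        n_union=len(set(d1) | set(d2)),
        n_consistent_intersection=len(consistent),
        agreement=len(consistent) / n,
        n_top=n,
    )


def run_comparisons(
    callsets: Mapping[tuple, CallSet], sites: Sequence[str]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Tally the four cross-site counts per site pair and intra-site counts.

    ``callsets`` is keyed by comparison descriptors: ``("intra", site)`` for
    the within-site A-vs-C comparison and ``(site1, type1, site2, type2)``
    for cross-site comparisons (the first-named site's sample is group1).
    Returns (per-pair counts with eFDR, per-site intra counts).
    """
    sites = [str(s) for s in sites]
    if len(sites) < 2:
        raise ValueError("need at least 2 sites")
    rows = []
    for s1, s2 in itertools.combinations(sites, 2):
        try:
            counts = ComparisonCounts(
                site_pair=(s1, s2),
                a1_vs_a2=len(callsets[(s1, "A", s2, "A")]),
                c1_vs_c2=len(callsets[(s1, "C", s2, "C")]),
                a1_vs_c2=len(callsets[(s1, "A", s2, "C")]),
                a2_vs_c1=len(callsets[(s2, "A", s1, "C")]),
            )
        except KeyError as exc:
            raise KeyError(f"missing cross-site comparison {exc.args[0]!r}") from None
        value, defined = efdr(counts)
        rows.append(
            {
                "site1": s1,
                "site2": s2,
                "a1_vs_a2": counts.a1_vs_a2,
                "c1_vs_c2": counts.c1_vs_c2,
                "a1_vs_c2": counts.a1_vs_c2,
                "a2_vs_c1": counts.a2_vs_c1,
                "efdr": value,
                "efdr_defined": defined,
            }
        )
    intra_rows = []
    for s in sites:
        if ("intra", s) not in callsets:
            raise KeyError(f"missing intra-site comparison for site {s!r}")
        intra_rows.append({"site": s, "n_calls": len(callsets[("intra", s)])})
    return pd.DataFrame(rows), pd.DataFrame(intra_rows)


def truth_metrics(calls: CallSet, truth: pd.DataFrame) -> dict[str, float]:
    """Realized FDR and sensitivity of a call set against simulation truth.

    Realized FDR = fraction of called genes that are not truly DE;
    sensitivity = fraction of truly DE genes called in the correct direction
    (the sign of the true log2 fold change).
    """
    t = truth.set_index("gene_id")
    missing = [g for g in calls.genes if g not in t.index]
    if missing:
        raise KeyError(f"called gene(s) absent from truth: {missing[:5]}")
    called = list(calls.genes)
    n_called = len(called)
    if n_called:
        false = (~t.loc[called, "is_de"]).sum()
        fdr = false / n_called
    else:
        fdr = 0.0
    de = t[t["is_de"]]
    if len(de):
        true_dir = np.where(de["true_log2fc"] < 0, "down", "up")
        hits = sum(
            1
            for g, d in zip(de.index, true_dir)
            if calls.genes.get(g) == d
        )
        sens = hits / len(de)
    else:
        sens = 0.0
    return {"fdr": float(fdr), "sensitivity": float(sens), "n_called": n_called}


def anova_sensitivity(count_table: pd.DataFrame) -> pd.DataFrame:
    """Two-way fixed-effects ANOVA of intra-site DE counts.

    ``count_table`` must have columns ``variant`` (expression-input variant),
    ``caller`` and ``site`` (the replicate axis) plus ``n_calls``, forming a
    complete two-factor layout.  Main effects only (no interaction): for each
    factor the sum of squares, F statistic and p-value.
    """
    required = {"variant", "caller", "site", "n_calls"}
    if not required <= set(count_table.columns):
        raise ValueError(f"count table needs columns {sorted(required)}")
    layout = count_table.groupby(["variant", "caller"]).size()
    if layout.nunique() != 1 or len(layout) != (
        count_table["variant"].nunique() * count_table["caller"].nunique()
    ):
        raise ValueError("incomplete two-factor layout")
    model = smf.ols("n_calls ~ C(variant) + C(caller)", data=count_table).fit()
    table = sm.stats.anova_lm(model, typ=2)
    table = table.rename(index={"C(variant)": "variant", "C(caller)": "caller", "Residual": "residual"})
    return table
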