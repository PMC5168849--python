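"""Two-group differential-expression callers emitting a uniform DE table.

Two built-in callers cover the two mainstream model families: a moderated-t
test on log-expression (empirical-Bayes variance shrinkage, limma-style) and
a negative-binomial Wald test on counts with trended dispersion shrinkage
(edgeR/DESeq2-style).  Both are deliberately simple, fully specified analogs;
the evaluation layer is caller-agnostic through the DE-table contract, and
external callers' outputs can be imported into the same contract.

DE-table columns: ``gene_id, log2fc, ave_expr, statistic, pvalue, qvalue,
direction`` with log2fc = group1 - group2 and direction = sign(log2fc).
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from debench.data_model import ExpressionMatrix

__all__ = ["bh_adjust", "moderated_t_caller", "nb_wald_caller", "import_de_table",
           "write_de_table", "DE_TABLE_COLUMNS"]

DE_TABLE_COLUMNS = ["gene_id", "log2fc", "ave_expr", "statistic", "pvalue", "qvalue", "direction"]


def bh_adjust(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    ``q_(i) = min_(j>=i) m * p_(j) / j`` on the sorted p-values, capped at 1,
    mapped back to input order.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must be finite and in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def _finalize(gene_ids, log2fc, ave_expr, statistic, pvalue) -> pd.DataFrame:
    q = bh_adjust(pvalue)
    return pd.DataFrame(
        {
            "gene_id": gene_ids,
            "log2fc": log2fc,
            "ave_expr": ave_expr,
            "statistic": statistic,
            "pvalue": pvalue,
            "qvalue": q,
            "direction": np.where(np.asarray(log2fc) < 0, "down", "up"),
        }
    )


def moderated_t_caller(
    matrix: ExpressionMatrix,
    group1: Sequence[str],
    group2: Sequence[str],
    prior_df: float = 4.0,
) -> pd.DataFrame:
    """Empirical-Bayes moderated two-sample t-test on log2 expression.

    Gene-wise pooled variances ``s_g^2`` (``d_g`` residual df) are shrunk
    toward their mean ``s0^2`` with ``prior_df`` pseudo-degrees of freedom:
    ``s~_g^2 = (prior_df*s0^2 + d_g*s_g^2) / (prior_df + d_g)``.  The t
    statistic ``M / (s~_g sqrt(1/n1 + 1/n2))`` is referred to a t distribution
    on ``prior_df + d_g`` df.  ``prior_df=0`` recovers the ordinary pooled
    two-sample t-test.  Genes with M = 0 and zero moderated variance get the
    null convention t = 0, p = 1.
    """
    if matrix.scale != "log2":
        raise ValueError("moderated_t_caller expects a log2-scale matrix")
    g1, g2 = list(group1), list(group2)
    n1, n2 = len(g1), len(g2)
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least 2 samples")
    y1 = matrix.values[:, matrix.column_indices(g1)]
    y2 = matrix.values[:, matrix.column_indices(g2)]
    m1, m2 = y1.mean(axis=1), y2.mean(axis=1)
    lfc = m1 - m2
    d = n1 + n2 - 2
    ss = ((y1 - m1[:, None]) ** 2).sum(axis=1) + ((y2 - m2[:, None]) ** 2).sum(axis=1)
    s2 = ss / d
    s0_2 = s2.mean()
    s2_mod = (prior_df * s0_2 + d * s2) / (prior_df + d)
    se = np.sqrt(s2_mod * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, lfc / np.where(se > 0, se, 1.0), 0.0)
    p = 2.0 * stats.t.sf(np.abs(t), df=prior_df + d)
    p = np.where(se > 0, p, 1.0)
    ave = np.concatenate([y1, y2], axis=1).mean(axis=1)
    return _finalize(matrix.gene_ids, lfc, ave, t, p)


def _fit_dispersion_trend(mu: np.ndarray, phi_hat: np.ndarray) -> np.ndarray:
    """Least-squares fit of phi = a + b/mu on informative genes, evaluated
    at every gene's mean (clipped at 0)."""
    ok = (mu > 1.0) & np.isfinite(phi_hat)
    if ok.sum() < 10:
        return np.full(mu.shape, max(float(np.nanmedian(phi_hat)), 0.0) if np.isfinite(np.nanmedian(phi_hat)) else 0.0)
    x = np.column_stack([np.ones(ok.sum()), 1.0 / mu[ok]])
    coef, *_ = np.linalg.lstsq(x, phi_hat[ok], rcond=None)
    with np.errstate(divide="ignore"):
        trend = coef[0] + coef[1] / np.maximum(mu, 1e-8)
    return np.clip(trend, 0.0, None)


def nb_wald_caller(
    matrix: ExpressionMatrix,
    size_factors: np.ndarray,
    group1: Sequence[str],
    group2: Sequence[str],
    dispersion_shrink: float = 0.5,
    prior: float = 0.5,
) -> pd.DataFrame:
    """Negative-binomial Wald test on normalized counts.

    Counts are normalized by relative effective library size (library sum x
    TMM factor, rescaled to geometric mean 1).  Gene-wise dispersions are
    method-of-moments estimates ``max(0, (v - mu) / mu^2)`` from the pooled
    within-group variance, shrunk toward a fitted ``a + b/mu`` mean-dispersion
    trend with weight ``dispersion_shrink``.  The Wald statistic is
    ``log2FC / SE`` with the delta-method SE of a log2 ratio of NB group
    means; p-values are two-sided normal.  All-zero genes get the convention
    log2fc = 0, p = 1.
    """
    if matrix.scale != "counts":
        raise ValueError("nb_wald_caller expects a counts-scale matrix")
    g1, g2 = list(group1), list(group2)
    n1, n2 = len(g1), len(g2)
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least 2 samples")
    size_factors = np.asarray(size_factors, dtype=float)
    eff = matrix.values.sum(axis=0) * size_factors
    rel = eff / np.exp(np.mean(np.log(eff)))
    norm = matrix.values / rel

    i1 = matrix.column_indices(g1)
    i2 = matrix.column_indices(g2)
    y1, y2 = norm[:, i1], norm[:, i2]
    mu1, mu2 = y1.mean(axis=1), y2.mean(axis=1)
    v1 = y1.var(axis=1, ddof=1)
    v2 = y2.var(axis=1, ddof=1)
    v_pool = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
    mu_pool = (mu1 + mu2) / 2.0
    with np.errstate(divide="ignore", invalid="ignore"):
        phi_hat = np.where(mu_pool > 0, (v_pool - mu_pool) / np.maximum(mu_pool, 1e-12) ** 2, 0.0)
    phi_hat = np.clip(phi_hat, 0.0, None)
    trend = _fit_dispersion_trend(mu_pool, phi_hat)
    phi = (1.0 - dispersion_shrink) * phi_hat + dispersion_shrink * trend

    lfc = np.log2((mu1 + prior) / (mu2 + prior))
    ln2sq = np.log(2.0) ** 2
    var1 = (mu1 + phi * mu1**2) / n1
    var2 = (mu2 + phi * mu2**2) / n2
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(
            var1 / np.maximum(mu1 + prior, 1e-12) ** 2 / ln2sq
            + var2 / np.maximum(mu2 + prior, 1e-12) ** 2 / ln2sq
        )
    nonnull = (mu1 + mu2) > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(nonnull & (se > 0), lfc / np.where(se > 0, se, 1.0), 0.0)
    p = 2.0 * stats.norm.sf(np.abs(z))
    p = np.where(nonnull & (se > 0), p, 1.0)
    lfc = np.where(nonnull, lfc, 0.0)
    ave = np.log2(mu_pool + prior)
    return _finalize(matrix.gene_ids, lfc, ave, z, p)


def import_de_table(
    path: str | Path, column_map: Mapping[str, str] | None = None
) -> pd.DataFrame:
    """Read an externally produced per-gene DE table into the shared contract.

    ``column_map`` maps contract names to the file's column names, e.g.
    ``{"pvalue": "PValue", "log2fc": "logFC"}``.  ``qvalue`` is recomputed by
    BH when absent; ``ave_expr`` defaults to 0 and ``statistic`` to NaN when
    missing; ``direction`` is derived from the sign of log2fc.
    """
    raw = pd.read_csv(path, sep="\t")
    column_map = dict(column_map or {})
    out = pd.DataFrame()
    for field in ("gene_id", "log2fc", "pvalue", "qvalue", "ave_expr", "statistic"):
        src = column_map.get(field, field)
        if src in raw.columns:
            out[field] = raw[src]
    for required in ("gene_id", "log2fc", "pvalue"):
        if required not in out.columns:
            raise ValueError(f"cannot map required column {required!r}")
    if out["gene_id"].duplicated().any():
        dups = out["gene_id"][out["gene_id"].duplicated()].tolist()
        raise ValueError(f"duplicated gene_id(s): {dups[:5]}")
    p = out["pvalue"].to_numpy(dtype=float)
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values outside [0, 1]")
    if "qvalue" not in out.columns:
        out["qvalue"] = bh_adjust(p)
    if "ave_expr" not in out.columns:
        out["ave_expr"] = 0.0
    if "statistic" not in out.columns:
        out["statistic"] = np.nan
    out["direction"] = np.where(out["log2fc"].to_numpy(dtype=float) < 0, "down", "up")
    return out[DE_TABLE_COLUMNS]


def write_de_table(table: pd.DataFrame, path: str | Path) -> None:
    """Serialize a DE table to TSV with 6 significant digits."""
    table[DE_TABLE_COLUMNS].to_csv(path, sep="\t", index=False, float_format="%.6g")
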