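"""Count-matrix container, TSV I/O, TMM normalization, log-CPM and M/A statistics.

A single normalization path (TMM size factors + prior-augmented log-CPM)
serves every downstream caller, so that differences between callers are not
confounded with differences between their internal normalizations.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

METADATA_COLUMNS = ("sample_id", "site", "sample_type", "replicate")

__all__ = [
    "ExpressionMatrix",
    "read_counts",
    "write_counts",
    "tmm_size_factors",
    "log_cpm",
    "compute_ma",
]


@dataclass
class ExpressionMatrix:
    """Gene x sample expression values with per-column metadata.

    Parameters
    ----------
    gene_ids
        Ordered, unique gene identifiers (rows).
    values
        ``(n_genes, n_samples)`` array. Non-negative integers on the
        ``"counts"`` scale, reals on the ``"log2"`` scale.
    samples
        Per-column metadata with columns ``sample_id``, ``site``,
        ``sample_type`` (``"A"`` or ``"C"``) and ``replicate``; row order
        matches the columns of ``values``.
    scale
        ``"counts"`` or ``"log2"``.
    """

    gene_ids: pd.Index
    values: np.ndarray
    samples: pd.DataFrame
    scale: str = "counts"

    def __post_init__(self) -> None:
        self.gene_ids = pd.Index(self.gene_ids, name="gene_id")
        self.values = np.asarray(self.values)
        self.samples = self.samples.reset_index(drop=True)
        self.validate()

    # -- contracts ---------------------------------------------------------
    def validate(self) -> None:
        if self.scale not in ("counts", "log2"):
            raise ValueError(f"unknown scale {self.scale!r}")
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D gene x sample array")
        if self.gene_ids.has_duplicates:
            dups = self.gene_ids[self.gene_ids.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene_ids: {dups[:5]}")
        if len(self.gene_ids) != self.values.shape[0]:
            raise ValueError("gene_ids length does not match value rows")
        missing = [c for c in METADATA_COLUMNS if c not in self.samples.columns]
        if missing:
            raise ValueError(f"sample metadata lacks columns {missing}")
        if self.samples["sample_id"].duplicated().any():
            raise ValueError("duplicate sample_ids in metadata")
        if len(self.samples) != self.values.shape[1]:
            raise ValueError(
                f"metadata covers {len(self.samples)} samples but matrix has "
                f"{self.values.shape[1]} columns"
            )
        if self.scale == "counts":
            if np.any(self.values < 0):
                raise ValueError("counts must be non-negative")
            if not np.issubdtype(self.values.dtype, np.integer):
                frac = self.values - np.floor(self.values)
                if np.any(frac != 0):
                    g, s = np.argwhere(frac != 0)[0]
                    raise ValueError(
                        f"non-integer count {self.values[g, s]} at gene "
                        f"{self.gene_ids[g]!r}, sample "
                        f"{self.samples['sample_id'].iloc[s]!r}"
                    )

    # -- conveniences ------------------------------------------------------
    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def sample_ids(self) -> list[str]:
        return self.samples["sample_id"].tolist()

    def column_indices(self, sample_ids: Sequence[str]) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.samples["sample_id"])}
        try:
            return np.array([lookup[s] for s in sample_ids], dtype=int)
        except KeyError as exc:
            raise KeyError(f"unknown sample_id {exc.args[0]!r}") from None

    def select_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        idx = self.column_indices(sample_ids)
        return ExpressionMatrix(
            gene_ids=self.gene_ids,
            values=self.values[:, idx],
            samples=self.samples.iloc[idx].reset_index(drop=True),
            scale=self.scale,
        )

    def ids_for(self, site: object | None = None, sample_type: str | None = None) -> list[str]:
        """Sample ids matching a site and/or sample type."""
        mask = np.ones(len(self.samples), dtype=bool)
        if site is not None:
            mask &= (self.samples["site"].astype(str) == str(site)).to_numpy()
        if sample_type is not None:
            mask &= (self.samples["sample_type"] == sample_type).to_numpy()
        return self.samples.loc[mask, "sample_id"].tolist()

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.samples["sample_id"])


@dataclass
class MAStats:
    """Per-gene M (log2 fold change) and A (average log2 expression)."""

    table: pd.DataFrame  # columns: gene_id, m_value, a_value

    @property
    def m(self) -> pd.Series:
        return self.table.set_index("gene_id")["m_value"]

    @property
    def a(self) -> pd.Series:
        return self.table.set_index("gene_id")["a_value"]


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_counts(path_counts: str | Path, path_metadata: str | Path) -> ExpressionMatrix:
    """Read a gene x sample count TSV plus its sample-metadata sidecar."""
    counts = pd.read_csv(path_counts, sep="\t", index_col=0)
    meta = pd.read_csv(path_metadata, sep="\t", dtype={"sample_id": str, "site": str})
    missing = [c for c in METADATA_COLUMNS if c not in meta.columns]
    if missing:
        raise ValueError(f"metadata file lacks columns {missing}")
    meta_ids = set(meta["sample_id"])
    absent = [s for s in counts.columns if s not in meta_ids]
    if absent:
        raise ValueError(f"metadata missing sample(s): {absent}")
    meta = meta.set_index("sample_id").loc[list(counts.columns)].reset_index()
    vals = counts.to_numpy()
    if not np.issubdtype(vals.dtype, np.integer):
        bad = vals != np.floor(vals)
        if bad.any():
            g, s = np.argwhere(bad)[0]
            raise ValueError(
                f"non-integer count {vals[g, s]!r} at gene {counts.index[g]!r}, "
                f"sample {counts.columns[s]!r}"
            )
        vals = vals.astype(np.int64)
    return ExpressionMatrix(gene_ids=counts.index, values=vals, samples=meta, scale="counts")


def write_counts(matrix: ExpressionMatrix, path_counts: str | Path, path_metadata: str | Path) -> None:
    """Write counts and metadata TSVs; round-trips with :func:`read_counts`."""
    matrix.to_frame().to_csv(path_counts, sep="\t")
    matrix.samples.loc[:, list(METADATA_COLUMNS)].to_csv(path_metadata, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------

def tmm_size_factors(
    matrix: ExpressionMatrix, trim_m: float = 0.30, trim_a: float = 0.05
) -> np.ndarray:
    """Trimmed-mean-of-M normalization factors (one per sample).

    M values are computed on library-normalized counts against a reference
    column (the one whose upper-quartile is closest to the mean upper-quartile),
    doubly trimmed (``trim_m`` on each M tail, ``trim_a`` on each A tail), and
    combined with precision weights.  Factors multiply the raw library size and
    are rescaled to geometric mean 1, so proportional columns get factor 1.
    """
    if matrix.scale != "counts":
        raise ValueError("tmm_size_factors requires a counts-scale matrix")
    x = matrix.values.astype(float)
    lib = x.sum(axis=0)
    if np.any(lib <= 0):
        bad = matrix.samples["sample_id"][lib <= 0].tolist()
        raise ValueError(f"all-zero sample(s): {bad}")
    uq = np.array([np.quantile(x[:, j][x[:, j] > 0] / lib[j], 0.75) if (x[:, j] > 0).any() else 0.0
                   for j in range(x.shape[1])])
    ref = int(np.argmin(np.abs(uq - uq.mean())))

    factors = np.ones(x.shape[1])
    xr = x[:, ref]
    for j in range(x.shape[1]):
        if j == ref:
            continue
        xs = x[:, j]
        keep = (xs > 0) & (xr > 0)
        if keep.sum() == 0:
            continue
        m = np.log2((xs[keep] / lib[j]) / (xr[keep] / lib[ref]))
        a = 0.5 * np.log2((xs[keep] / lib[j]) * (xr[keep] / lib[ref]))
        # asymptotic binomial variance of M; weights are its inverse
        w = 1.0 / ((lib[j] - xs[keep]) / (lib[j] * xs[keep])
                   + (lib[ref] - xr[keep]) / (lib[ref] * xr[keep]))
        n = m.size
        m_rank = pd.Series(m).rank(method="first").to_numpy()
        a_rank = pd.Series(a).rank(method="first").to_numpy()
        sel = (
            (m_rank > trim_m * n) & (m_rank <= (1 - trim_m) * n)
            & (a_rank > trim_a * n) & (a_rank <= (1 - trim_a) * n)
        )
        if not sel.any():
            continue
        factors[j] = 2.0 ** (np.sum(w[sel] * m[sel]) / np.sum(w[sel]))
    factors = factors / np.exp(np.mean(np.log(factors)))
    return factors


def log_cpm(
    matrix: ExpressionMatrix, size_factors: np.ndarray, prior: float = 0.5
) -> ExpressionMatrix:
    """Prior-augmented log2 counts-per-million on TMM-effective library sizes.

    The prior count is scaled by the relative effective library size (the
    edgeR convention), so columns that are exact scalar multiples of one
    another map to identical log-CPM columns.
    """
    if matrix.scale != "counts":
        raise ValueError("log_cpm requires a counts-scale matrix")
    size_factors = np.asarray(size_factors, dtype=float)
    if np.any(size_factors <= 0):
        raise ValueError("size factors must be positive")
    lib = matrix.values.sum(axis=0).astype(float) * size_factors
    prior_scaled = prior * lib / lib.mean()
    vals = np.log2((matrix.values + prior_scaled) / (lib + 2 * prior_scaled) * 1e6)
    return ExpressionMatrix(
        gene_ids=matrix.gene_ids, values=vals, samples=matrix.samples.copy(), scale="log2"
    )


def effective_library_sizes(matrix: ExpressionMatrix, size_factors: np.ndarray) -> np.ndarray:
    """Raw library size times TMM factor, per column."""
    return matrix.values.sum(axis=0).astype(float) * np.asarray(size_factors, dtype=float)


# ---------------------------------------------------------------------------
# M / A statistics
# ---------------------------------------------------------------------------

def compute_ma(
    matrix: ExpressionMatrix, group1: Sequence[str], group2: Sequence[str]
) -> MAStats:
    """Per-gene M (mean(group1) - mean(group2)) and A (mean over both groups).

    By convention group1 is the first-named sample of a comparison label
    ("A-vs-C" puts A first), so genes down-regulated in A have M < 0.
    """
    if matrix.scale != "log2":
        raise ValueError("compute_ma requires a log2-scale matrix")
    g1, g2 = list(group1), list(group2)
    if not g1 or not g2:
        raise ValueError("both groups must be nonempty")
    if set(g1) & set(g2):
        raise ValueError(f"groups overlap: {sorted(set(g1) & set(g2))}")
    i1 = matrix.column_indices(g1)
    i2 = matrix.column_indices(g2)
    m1 = matrix.values[:, i1].mean(axis=1)
    m2 = matrix.values[:, i2].mean(axis=1)
    a = matrix.values[:, np.concatenate([i1, i2])].mean(axis=1)
    return MAStats(
        pd.DataFrame({"gene_id": matrix.gene_ids, "m_value": m1 - m2, "a_value": a})
    )
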