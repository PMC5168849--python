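"""Surrogate-variable analysis by residual SVD with a parallel-analysis rule.

Latent technical confounders (library-preparation batches and the like) leave
low-rank structure in the part of log-expression that the known design does
not explain.  We estimate that structure by SVD of the design residuals and
regress it out gene by gene while protecting the sample-type effect — the
"remove latent structure orthogonal to the design" contract, with every step
explicit and testable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from debench.data_model import ExpressionMatrix

__all__ = ["SurrogateModel", "estimate_surrogates", "remove_confounders"]


@dataclass
class SurrogateModel:
    """Estimated latent factors (orthonormal sample-space columns) and loadings."""

    n_factors: int
    factors: np.ndarray  # sample x k, orthonormal columns
    loadings: np.ndarray  # gene x k
    sample_ids: list[str]

    def save(self, prefix: str | Path) -> None:
        prefix = Path(prefix)
        pd.DataFrame(
            self.factors,
            index=self.sample_ids,
            columns=[f"sv{i+1}" for i in range(self.n_factors)],
        ).to_csv(prefix.with_suffix(".factors.tsv"), sep="\t", float_format="%.6g")
        prefix.with_suffix(".json").write_text(
            json.dumps({"n_factors": self.n_factors, "n_samples": len(self.sample_ids)})
        )


def _design_matrix(sample_types: pd.Series) -> np.ndarray:
    """Intercept + sample-type indicator (the protected covariate)."""
    ind = (sample_types.to_numpy() == "C").astype(float)
    return np.column_stack([np.ones(ind.size), ind])


def _residuals(values: np.ndarray, design: np.ndarray) -> np.ndarray:
    beta, *_ = np.linalg.lstsq(design, values.T, rcond=None)
    return values - (design @ beta).T


def _column_standardize(resid: np.ndarray) -> np.ndarray:
    sd = resid.std(axis=0, ddof=1)
    sd = np.where(sd > 0, sd, 1.0)
    return resid / sd


def estimate_surrogates(
    matrix: ExpressionMatrix,
    k: int | str = "auto",
    n_perm: int = 20,
    alpha: float = 0.05,
    seed: int = 0,
) -> SurrogateModel:
    """Estimate surrogate variables from design residuals.

    Per gene, the least-squares fit on the sample-type design is removed; the
    top right singular vectors of the residual matrix (columns standardized to
    unit variance) become the factors.  Column standardization matters:
    sequencing depth varies by column and the count noise is heteroskedastic,
    which puts genuine but purely scale-type structure into the raw residuals;
    standardizing leaves only cross-gene correlation structure, which is what
    a latent confounder produces.

    With ``k="auto"`` the number of factors is chosen by parallel analysis:
    the k-th residual singular value must exceed the ``1 - alpha`` quantile of
    k-th singular values obtained from ``n_perm`` row-wise permutations of the
    residuals (re-residualized and re-standardized; counting from the top
    until the first failure).
    """
    if matrix.scale != "log2":
        raise ValueError("estimate_surrogates expects a log2-scale matrix")
    design = _design_matrix(matrix.samples["sample_type"])
    rank = np.linalg.matrix_rank(design)
    max_k = matrix.n_samples - rank
    if matrix.n_samples - rank < 3:
        raise ValueError("need at least 3 samples beyond the design rank")
    if isinstance(k, int) and k > max_k:
        raise ValueError(f"k={k} exceeds admissible rank {max_k}")

    resid = _residuals(matrix.values, design)
    std = _column_standardize(resid)
    s, vt = np.linalg.svd(std, full_matrices=False)[1:]

    if k == "auto":
        if np.allclose(s, 0.0):
            n_factors = 0
        else:
            rng = np.random.default_rng(seed)
            perm_s = np.empty((n_perm, s.size))
            for p in range(n_perm):
                perm = rng.permuted(resid, axis=1)
                perm = _column_standardize(_residuals(perm, design))
                perm_s[p] = np.linalg.svd(perm, compute_uv=False)
            thresh = np.quantile(perm_s, 1.0 - alpha, axis=0)
            n_factors = 0
            for i in range(min(s.size, max_k)):
                if s[i] > thresh[i]:
                    n_factors += 1
                else:
                    break
    else:
        n_factors = int(k)

    factors = vt[:n_factors].T  # sample x k, orthonormal
    loadings = resid @ factors  # gene x k
    return SurrogateModel(
        n_factors=n_factors,
        factors=factors,
        loadings=loadings,
        sample_ids=matrix.sample_ids,
    )


def remove_confounders(matrix: ExpressionMatrix, model: SurrogateModel) -> ExpressionMatrix:
    """Regress estimated factors out of log-expression, keeping the design effect.

    Per gene, a joint least-squares fit on [design | factors] is computed and
    only the factor contribution subtracted, so any signal attributable to
    sample type survives.  With an empty model the input is returned unchanged
    (a copy).  The operation is idempotent.
    """
    if matrix.scale != "log2":
        raise ValueError("remove_confounders expects a log2-scale matrix")
    if model.sample_ids != matrix.sample_ids:
        raise ValueError("model was estimated on a different sample set")
    if model.n_factors == 0:
        return ExpressionMatrix(
            gene_ids=matrix.gene_ids,
            values=matrix.values.copy(),
            samples=matrix.samples.copy(),
            scale="log2",
        )
    design = _design_matrix(matrix.samples["sample_type"])
    x = np.column_stack([design, model.factors])
    beta, *_ = np.linalg.lstsq(x, matrix.values.T, rcond=None)
    factor_part = (model.factors @ beta[design.shape[1]:, :]).T
    return ExpressionMatrix(
        gene_ids=matrix.gene_ids,
        values=matrix.values - factor_part,
        samples=matrix.samples.copy(),
        scale="log2",
    )
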