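"""Synthetic multi-site reference-mixture RNA-seq count generator.

Emulates the titration benchmark design: two well-characterized reference
RNA samples, A and B, and their 3:1 mixture C.  Only samples A and C are
"sequenced", at ``n_sites`` sites with ``replicates_per_sample`` technical
replicates each.  Because C contains 3 parts A, no gene can be up-regulated
in A by more than 4/3-fold, while down-regulation in A is unbounded — the
property every downstream specificity analysis leans on.

Counts are negative binomial with a gene-wise dispersion trend
``phi(mu) = phi0 + phi1/mu`` (variance ``mu + phi*mu^2``).  Hidden technical
confounders (library-preparation-like) are injected as site-level latent
factors: each site draws a score per factor, shared by all of its columns,
and a sparse gene-loading vector multiplies the NB mean by
``exp(sum_k lambda_gk * f_ks)``.  The realized loadings and scores are
returned so recovery can be tested.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from debench.data_model import ExpressionMatrix

__all__ = [
    "GeneProfile",
    "ProfileParams",
    "MixtureDesign",
    "StudyDesign",
    "sample_gene_profiles",
    "expected_mixture_mean",
    "true_log2fc",
    "simulate_counts",
    "ConfounderRecord",
]

#: Size of the full human gene universe used as the default simulation scale.
DEFAULT_UNIVERSE = 55_674

#: Effect-strength rule shared by ground truth and call filtering.
DE_LOG2FC_THRESHOLD = 1.0


@dataclass(frozen=True)
class GeneProfile:
    """Per-gene abundance in the two pure reference samples plus dispersion."""

    gene_id: str
    a_mean: float  # expected normalized expression in pure sample A
    b_mean: float  # expected normalized expression in pure sample B
    dispersion: float  # NB phi: variance = mu + phi * mu^2

    def __post_init__(self) -> None:
        if self.a_mean < 0 or self.b_mean < 0:
            raise ValueError(f"{self.gene_id}: negative abundance")
        if self.dispersion < 0:
            raise ValueError(f"{self.gene_id}: negative dispersion")


@dataclass(frozen=True)
class MixtureDesign:
    """Mixing proportion of sample A within sample C (3:1 by default)."""

    p_a: float = 0.75

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_a <= 1.0:
            raise ValueError("p_a must lie in [0, 1]")

    @property
    def p_b(self) -> float:
        return 1.0 - self.p_a


@dataclass(frozen=True)
class ProfileParams:
    """Hyper-parameters of the gene-profile generator.

    Abundances are log-normal on the natural-log scale.  ``a_only_fraction``
    and ``b_only_fraction`` of genes are expressed in one reference only
    (deterministic allocation, so realized fractions match to +-1 gene).
    For shared genes A and B abundances are drawn independently, which at
    ``log_sd`` ~ 2 yields a realistic spread of fold changes including a few
    thousand genes (per 20k) beyond the 2-fold call threshold.
    """

    log_mean: float = float(np.log(70.0))
    log_sd: float = 2.0
    a_only_fraction: float = 0.05
    b_only_fraction: float = 0.05
    phi0: float = 0.01
    phi1: float = 2.0

    def __post_init__(self) -> None:
        if self.log_sd < 0 or self.phi0 < 0 or self.phi1 < 0:
            raise ValueError("negative hyper-parameter")
        if min(self.a_only_fraction, self.b_only_fraction) < 0 or (
            self.a_only_fraction + self.b_only_fraction > 1
        ):
            raise ValueError("exclusive-gene fractions must be in [0,1] and sum <= 1")


@dataclass(frozen=True)
class StudyDesign:
    """Multi-site study layout and technical-noise settings."""

    n_sites: int = 6
    replicates_per_sample: int = 4
    library_size_mean: float = 1e7
    library_size_cv: float = 0.2
    n_confounders_per_site: int = 2
    confounder_loading_sparsity: float = 0.3  # fraction of genes with nonzero loading
    confounder_sd: float = 0.5  # SD of nonzero natural-log loadings
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sites < 2:
            raise ValueError("n_sites must be >= 2 (inter-site comparisons need pairs)")
        if self.replicates_per_sample < 1:
            raise ValueError("replicates_per_sample must be positive")
        if self.library_size_mean <= 0:
            raise ValueError("library_size_mean must be positive")
        if self.library_size_cv < 0 or self.confounder_sd < 0:
            raise ValueError("negative noise parameter")
        if not 0.0 <= self.confounder_loading_sparsity <= 1.0:
            raise ValueError("confounder_loading_sparsity must lie in [0,1]")
        if self.n_confounders_per_site < 0:
            raise ValueError("n_confounders_per_site must be >= 0")


@dataclass
class ConfounderRecord:
    """Realized latent-factor structure of one simulation, for recovery tests."""

    loadings: np.ndarray  # gene x k, natural-log scale
    site_scores: np.ndarray  # site x k
    column_scores: np.ndarray  # sample x k (site scores broadcast to columns)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "loadings": self.loadings.tolist(),
            "site_scores": self.site_scores.tolist(),
            "column_scores": self.column_scores.tolist(),
        }
        Path(path).write_text(json.dumps(payload))


# ---------------------------------------------------------------------------
# Gene profiles and ground truth
# ---------------------------------------------------------------------------

def sample_gene_profiles(
    n_genes: int, params: ProfileParams | None = None, seed: int = 0
) -> list[GeneProfile]:
    """Draw per-gene pure-sample abundances and dispersions.

    Allocation of A-only / B-only / shared genes is deterministic given
    ``n_genes`` (rounded counts); abundances are log-normal draws.  The
    dispersion trend is evaluated at each gene's pure-sample average
    ``(a_mean + b_mean) / 2``.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    params = params or ProfileParams()
    rng = np.random.default_rng(seed)
    n_a = int(round(params.a_only_fraction * n_genes))
    n_b = int(round(params.b_only_fraction * n_genes))
    n_shared = n_genes - n_a - n_b

    a = np.zeros(n_genes)
    b = np.zeros(n_genes)
    a[:n_a] = rng.lognormal(params.log_mean, params.log_sd, n_a)
    b[n_a : n_a + n_b] = rng.lognormal(params.log_mean, params.log_sd, n_b)
    a[n_a + n_b :] = rng.lognormal(params.log_mean, params.log_sd, n_shared)
    b[n_a + n_b :] = rng.lognormal(params.log_mean, params.log_sd, n_shared)

    mu = (a + b) / 2.0
    with np.errstate(divide="ignore"):
        phi = params.phi0 + np.where(mu > 0, params.phi1 / np.maximum(mu, 1e-300), 0.0)
    width = len(str(n_genes))
    return [
        GeneProfile(f"g{i:0{width}d}", float(a[i]), float(b[i]), float(phi[i]))
        for i in range(n_genes)
    ]


def expected_mixture_mean(profile: GeneProfile, mix: MixtureDesign) -> float:
    """Expected abundance of a gene in mixture sample C."""
    return mix.p_a * profile.a_mean + mix.p_b * profile.b_mean


def true_log2fc(
    profiles: Sequence[GeneProfile], mix: MixtureDesign = MixtureDesign()
) -> pd.DataFrame:
    """Ground-truth A-vs-C log2 fold change and DE label per gene.

    ``true_log2fc = log2(a_mean / (p_a*a_mean + p_b*b_mean))``; genes present
    only in B get ``-inf`` and are DE.  A gene absent from both references has
    an undefined ratio and is flagged invalid (``valid=False``, NaN effect).
    The DE label uses the same ``|log2FC| > 1`` rule as the call filter so
    truth and calls share one effect-size scale.
    """
    if not len(profiles):
        raise ValueError("profiles must be nonempty")
    a = np.array([p.a_mean for p in profiles])
    b = np.array([p.b_mean for p in profiles])
    c = mix.p_a * a + mix.p_b * b
    valid = c > 0
    lfc = np.full(a.shape, np.nan)
    pos = valid & (a > 0)
    lfc[pos] = np.log2(a[pos] / c[pos])
    lfc[valid & (a == 0)] = -np.inf
    is_de = np.zeros(a.shape, dtype=bool)
    is_de[valid] = np.abs(lfc[valid]) > DE_LOG2FC_THRESHOLD
    return pd.DataFrame(
        {
            "gene_id": [p.gene_id for p in profiles],
            "a_mean": a,
            "b_mean": b,
            "true_log2fc": lfc,
            "is_de": is_de,
            "valid": valid,
        }
    )


# ---------------------------------------------------------------------------
# Count simulation
# ---------------------------------------------------------------------------

def _nb_draw(rng: np.random.Generator, mu: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """NB(mu, phi) with variance mu + phi mu^2; phi=0 falls back to Poisson."""
    counts = np.zeros(mu.shape, dtype=np.int64)
    pois = phi <= 0
    if pois.any():
        counts[pois] = rng.poisson(mu[pois])
    nb = ~pois
    if nb.any():
        r = 1.0 / phi[nb]
        p = r / (r + mu[nb])
        counts[nb] = rng.negative_binomial(r, p)
    return counts


def simulate_counts(
    profiles: Sequence[GeneProfile],
    design: StudyDesign = StudyDesign(),
    mix: MixtureDesign = MixtureDesign(),
    seed: int | None = None,
) -> tuple[ExpressionMatrix, ConfounderRecord]:
    """Simulate the full gene x (site x sample-type x replicate) count matrix.

    Column means are ``size_factor * type_mean * exp(sum_k lambda_gk f_ks)``
    where the size factor is the drawn library size relative to the nominal
    mean, type means are the pure-A or mixture-C abundances, and the
    exponential tilt carries the site-level confounders.
    """
    seed = design.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    a = np.array([p.a_mean for p in profiles])
    b = np.array([p.b_mean for p in profiles])
    phi = np.array([p.dispersion for p in profiles])
    c = mix.p_a * a + mix.p_b * b
    n_genes = len(profiles)
    k = design.n_confounders_per_site

    # latent confounders: sparse gene loadings, one score per (factor, site)
    loadings = np.zeros((n_genes, k))
    if k > 0:
        nz = rng.random((n_genes, k)) < design.confounder_loading_sparsity
        loadings[nz] = rng.normal(0.0, design.confounder_sd, nz.sum())
    site_scores = rng.standard_normal((design.n_sites, k)) if k > 0 else np.zeros((design.n_sites, 0))

    # library sizes, log-normal with the requested mean and CV
    n_cols = design.n_sites * 2 * design.replicates_per_sample
    if design.library_size_cv > 0:
        sigma2 = np.log1p(design.library_size_cv**2)
        libs = rng.lognormal(
            np.log(design.library_size_mean) - sigma2 / 2.0, np.sqrt(sigma2), n_cols
        )
    else:
        libs = np.full(n_cols, design.library_size_mean)
    if np.any(libs <= 0):
        raise ValueError("library sizes must be positive")

    # scale profiles so a nominal library carries the nominal total depth
    total = (a + c).sum() / 2.0
    depth_scale = design.library_size_mean / total if total > 0 else 1.0

    cols = []
    meta = []
    col_scores = []
    j = 0
    for s in range(1, design.n_sites + 1):
        tilt = np.exp(loadings @ site_scores[s - 1]) if k > 0 else 1.0
        for stype, base in (("A", a), ("C", c)):
            for r in range(1, design.replicates_per_sample + 1):
                sf = libs[j] / design.library_size_mean
                mu = sf * depth_scale * base * tilt
                cols.append(_nb_draw(rng, mu, phi))
                meta.append((f"site{s}_{stype}_rep{r}", str(s), stype, r))
                col_scores.append(site_scores[s - 1])
                j += 1

    values = np.column_stack(cols)
    samples = pd.DataFrame(meta, columns=["sample_id", "site", "sample_type", "replicate"])
    matrix = ExpressionMatrix(
        gene_ids=pd.Index([p.gene_id for p in profiles]),
        values=values,
        samples=samples,
        scale="counts",
    )
    record = ConfounderRecord(
        loadings=loadings,
        site_scores=site_scores,
        column_scores=np.array(col_scores).reshape(n_cols, k),
    )
    return matrix, record


def write_truth(truth: pd.DataFrame, path: str | Path) -> None:
    """Serialize a ground-truth table to TSV (6 significant digits)."""
    truth.to_csv(path, sep="\t", index=False, float_format="%.6g")
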