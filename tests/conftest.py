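import numpy as np
import pandas as pd
import pytest

from debench.data_model import ExpressionMatrix


def make_matrix(values, scale="counts", sites=None, types=None):
    """Build a small ExpressionMatrix with auto-generated metadata."""
    values = np.asarray(values)
    n_genes, n_samples = values.shape
    sites = sites or ["1"] * n_samples
    types = types or ["A"] * n_samples
    samples = pd.DataFrame(
        {
            "sample_id": [f"s{i}" for i in range(n_samples)],
            "site": sites,
            "sample_type": types,
            "replicate": list(range(1, n_samples + 1)),
        }
    )
    return ExpressionMatrix(
        gene_ids=pd.Index([f"g{i}" for i in range(n_genes)]),
        values=values,
        samples=samples,
        scale=scale,
    )


def make_de_table(gene_ids, log2fc, qvalue, ave_expr=None, pvalue=None):
    """Build a minimal DE table for filter/evaluation tests."""
    n = len(gene_ids)
    log2fc = np.asarray(log2fc, dtype=float)
    return pd.DataFrame(
        {
            "gene_id": gene_ids,
            "log2fc": log2fc,
            "ave_expr": np.zeros(n) if ave_expr is None else np.asarray(ave_expr, float),
            "statistic": np.zeros(n),
            "pvalue": np.asarray(qvalue, float) if pvalue is None else np.asarray(pvalue, float),
            "qvalue": np.asarray(qvalue, float),
            "direction": np.where(log2fc < 0, "down", "up"),
        }
    )


@pytest.fixture(scope="session")
def small_benchmark():
    """One small but complete benchmark run shared by slower tests.

    5,000 genes, 6 sites x 4 technical replicates, site confounders on,
    moderated-t caller only.
    """
    from debench.orchestration import RunConfig, run_benchmark

    cfg = RunConfig(seed=7)
    cfg.simulation.n_genes = 5000
    cfg.analysis.callers = ["moderated_t"]
    return run_benchmark(cfg)
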