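import numpy as np
import pandas as pd
import pytest

from cerna_recur.normio import ExpressionMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


def make_matrix(values, groups=None, flags=None, gene_prefix="g", sample_prefix="s"):
    """Build an ExpressionMatrix from a plain array (linear intensities)."""
    values = np.asarray(values, float)
    n_genes, n_samples = values.shape
    gene_ids = [f"{gene_prefix}{i + 1}" for i in range(n_genes)]
    sample_ids = [f"{sample_prefix}{j + 1}" for j in range(n_samples)]
    if groups is None:
        groups = ["A"] * n_samples
    vals = pd.DataFrame(values, index=gene_ids, columns=sample_ids)
    grp = pd.Series(list(groups), index=sample_ids)
    fl = None
    if flags is not None:
        fl = pd.DataFrame(np.asarray(flags, dtype=object), index=gene_ids,
                          columns=sample_ids)
    return ExpressionMatrix(vals, grp, fl)


@pytest.fixture
def two_group_matrix(rng):
    """8 genes x 8 samples (4 A + 4 B), lognormal noise around 2^8."""
    log2 = rng.normal(8.0, 0.2, size=(8, 8))
    return make_matrix(np.exp2(log2), groups="AAAABBBB")
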