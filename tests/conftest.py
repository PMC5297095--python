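import numpy as np
import pandas as pd
import pytest

from seedgcn.expression import ExpressionMatrix


def make_matrix(values, gene_ids=None, sample_ids=None, groups=None):
    """Build an ExpressionMatrix from a plain array with sensible defaults."""
    values = np.asarray(values, dtype=float)
    n_genes, n_samples = values.shape
    gene_ids = gene_ids or [f"G{i}" for i in range(n_genes)]
    sample_ids = sample_ids or [f"S{i}" for i in range(n_samples)]
    df = pd.DataFrame(values, index=pd.Index(gene_ids, name="gene_id"),
                      columns=sample_ids)
    if groups is None:
        half = n_samples // 2
        groups = {s: ("case" if i < half else "control")
                  for i, s in enumerate(sample_ids)}
    elif isinstance(groups, (list, tuple)):
        groups = dict(zip(sample_ids, groups))
    return ExpressionMatrix(values=df, sample_groups=groups)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def two_group_matrix(rng):
    """60 genes x 24 samples (12 case / 12 control), 10 genes shifted up."""
    x = rng.normal(7.0, 0.6, size=(60, 24))
    x[:10, :12] += 1.5
    return make_matrix(x)
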