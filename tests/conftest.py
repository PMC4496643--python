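import numpy as np
import pytest

from coexsearch import ExpressionMatrix


@pytest.fixture
def tiny_matrix() -> ExpressionMatrix:
    """A handcrafted 5-gene, 4-sample matrix with one missing entry."""
    values = np.array([
        [1.0, 2.0, 3.0, 4.0],
        [3.0, 4.0, 5.0, 6.0],
        [2.0, 2.0, 2.0, 2.0],
        [1.0, np.nan, 7.0, 5.0],
        [9.0, 1.0, 4.0, 0.0],
    ])
    return ExpressionMatrix(
        ["ga", "gb", "gc", "gd", "ge"], ["s1", "s2", "s3", "s4"], values
    )


def random_matrix(rng: np.random.Generator, n_genes: int, n_samples: int,
                  missing_frac: float = 0.0) -> ExpressionMatrix:
    """Dense Gaussian matrix helper shared across test modules."""
    values = rng.normal(size=(n_genes, n_samples))
    if missing_frac > 0:
        mask = rng.random(values.shape) < missing_frac
        # keep at least 3 present per row so every gene stays scoreable
        for i in range(n_genes):
            present = np.flatnonzero(~mask[i])
            if present.size < 3:
                mask[i, rng.choice(n_samples, size=3, replace=False)] = False
        values[mask] = np.nan
    gene_ids = [f"g{i:04d}" for i in range(n_genes)]
    labels = [f"s{j}" for j in range(n_samples)]
    return ExpressionMatrix(gene_ids, labels, values)
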