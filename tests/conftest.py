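import numpy as np
import pytest
from hypothesis import settings

from attbiomarker.expression_io import LabeledExpressionMatrix

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def make_matrix(values, labels, prefix="s"):
    values = np.asarray(values, dtype=float)
    q, p = values.shape
    return LabeledExpressionMatrix(
        values=values,
        sample_ids=[f"{prefix}{i}" for i in range(q)],
        gene_ids=[f"g{j}" for j in range(p)],
        labels=np.asarray(labels, dtype=int),
    )


@pytest.fixture
def tiny_matrix():
    """4 samples x 3 genes; gene g0 separates the classes."""
    return make_matrix(
        [[0.0, 5.0, 1.0],
         [0.5, 5.1, 2.0],
         [3.0, 5.2, 1.5],
         [3.5, 4.9, 2.5]],
        [0, 0, 1, 1],
    )


@pytest.fixture
def random_labeled_matrix(rng):
    """60 samples x 30 genes, labels balanced, 3 informative genes."""
    n, p = 60, 30
    y = np.repeat([0, 1], n // 2)
    X = rng.normal(size=(n, p))
    X[:, :3] += 1.8 * y[:, None]
    return make_matrix(X, y)
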