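import numpy as np
import pytest

from gnmfdma import AssociationMatrix, SimilarityMatrix


def random_similarity(rng, n, ids=None, kind="fused_drug"):
    """Random valid similarity matrix: symmetric, [0,1], unit diagonal."""
    A = rng.uniform(size=(n, n))
    A = (A + A.T) / 2.0
    np.fill_diagonal(A, 1.0)
    return SimilarityMatrix(ids or [f"e{i}" for i in range(n)], A, kind=kind)


def random_association(rng, n, m, density=0.3):
    Y = (rng.uniform(size=(n, m)) < density).astype(float)
    # guarantee at least one association so "known neighbor" sets are nonempty
    if Y.sum() == 0:
        Y[0, 0] = 1.0
    return AssociationMatrix(
        [f"d{i}" for i in range(n)], [f"m{j}" for j in range(m)], Y
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_dataset():
    """Small but non-trivial dataset exercising the whole pipeline quickly."""
    import gnmfdma

    return gnmfdma.generate(n=15, m=25, r=3, density=0.1, noise=0.2, seed=7)
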