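import numpy as np
import pytest

from paca.datamodel import DataMatrix


def random_pair(m=30, n1=5, n0=5, seed=0):
    """A feature-aligned random (cases, controls) pair.

    Left uncentered so the sample Gram matrices are full rank — the
    ridge-free CCA oracle comparisons need well-conditioned instances.
    """
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((m, n1))
    Y = rng.standard_normal((m, n0))
    feats = np.array([f"f{i}" for i in range(m)], dtype=object)
    Xdm = DataMatrix(X, feats, np.array([f"c{i}" for i in range(n1)], dtype=object), "target")
    Ydm = DataMatrix(Y, feats.copy(), np.array([f"k{i}" for i in range(n0)], dtype=object), "background")
    return Xdm, Ydm


@pytest.fixture
def small_pair():
    return random_pair()


@pytest.fixture
def tiny_matrix():
    values = np.array([[1.0, 2.0, 3.0], [4.0, 5.5, 6.0], [-1.0, 0.5, 2.25]])
    return DataMatrix(
        values,
        np.array(["gene_a", "gene_b", "gene_c"], dtype=object),
        np.array(["s1", "s2", "s3"], dtype=object),
        "target",
    )
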