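import numpy as np
import pytest

from gaos2fs import SparseFeatureBlock, inject_mcar


@pytest.fixture
def rank1_block():
    """Noiseless rank-1 50x20 block with 30% of cells hidden (MCAR)."""
    rng = np.random.default_rng(0)
    R = rng.standard_normal((50, 1)) @ rng.standard_normal((20, 1)).T
    block = inject_mcar(R, 0.3, seed=1)
    return block, R


@pytest.fixture
def separable_toy():
    """Two well-separated Gaussian clouds in 2-D; labels 0/1."""
    rng = np.random.default_rng(42)
    X0 = rng.normal(0.0, 0.3, size=(30, 2))
    X1 = rng.normal(5.0, 0.3, size=(30, 2))
    X = np.vstack([X0, X1])
    y = np.array([0] * 30 + [1] * 30)
    return X, y


def make_block(values, mask=None, ids=None):
    values = np.asarray(values, dtype=float)
    if mask is None:
        mask = np.ones_like(values, dtype=bool)
    if ids is None:
        ids = list(range(values.shape[1]))
    return SparseFeatureBlock(values=values, mask=mask, feature_ids=ids)
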