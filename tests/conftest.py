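import numpy as np
import pytest

from robustsam import TwoGroupExpression


def make_expr(X, Y, gene_ids=None):
    """Assemble a TwoGroupExpression from control/treatment blocks."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if gene_ids is None:
        gene_ids = np.array([f"g{i}" for i in range(X.shape[0])])
    group = np.array(["control"] * X.shape[1] + ["treatment"] * Y.shape[1])
    return TwoGroupExpression(
        values=np.hstack([X, Y]), gene_ids=gene_ids, group=group
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def random_expr(rng):
    """A 60-gene random matrix with 4 control / 5 treatment replicates."""
    return make_expr(
        rng.normal(8.0, 1.0, size=(60, 4)), rng.normal(8.0, 1.0, size=(60, 5))
    )
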