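import numpy as np
import pytest

from ordsmooth.metrics import ScoreTable


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_score_table(rng, n, K, concentration=1.0):
    """A random score table whose scores are loosely informative of y_true."""
    y = rng.integers(0, K, size=n)
    # ensure at least two classes are present
    if len(np.unique(y)) < 2:
        y[0], y[1] = 0, 1
    scores = rng.random((n, K)) + concentration * np.eye(K)[y] * rng.random((n, 1))
    return ScoreTable(ids=np.arange(n), y_true=y, scores=scores)


def random_confusion(rng, K, max_count=20):
    """A random confusion matrix with a non-empty total."""
    cm = rng.integers(0, max_count, size=(K, K))
    if cm.sum() == 0:
        cm[0, 0] = 1
    return cm
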