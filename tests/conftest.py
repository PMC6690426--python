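import numpy as np
import pytest

from exactlogrank import validate_dataset


@pytest.fixture
def d1():
    """Worked two-group example: A events at (1, 2), B events at (3, 4)."""
    return validate_dataset([1, 2, 3, 4], [1, 1, 1, 1], ["A", "A", "B", "B"])


def random_dataset(rng, n=None, n_groups=2, censor_prob=0.3, round_to=None):
    """Random exponential dataset with all groups represented."""
    n = int(rng.integers(max(n_groups + 1, 4), 40)) if n is None else n
    while True:
        t = rng.exponential(1.0, n)
        if round_to is not None:
            t = np.round(t, round_to)
        e = rng.random(n) >= censor_prob
        g = rng.integers(0, n_groups, n)
        if e.any() and len(set(g.tolist())) == n_groups:
            return validate_dataset(t, e, g)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
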