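import numpy as np
import pytest

from roughns import DecisionTable, Partition


@pytest.fixture
def toy_table() -> DecisionTable:
    """Four objects over attributes a, b, c; b alone determines the decision."""
    return DecisionTable(
        attributes=["a", "b", "c"],
        values=np.array([[0, 0, 0], [0, 1, 1], [1, 0, 1], [1, 1, 0]]),
        decision=np.array([0, 1, 0, 1]),
    )


@pytest.fixture
def two_block_partition() -> Partition:
    """Blocks {0,1} and {2,3}."""
    return Partition(
        blocks=[np.array([0, 1]), np.array([2, 3])],
        block_of=np.array([0, 0, 1, 1]),
    )


def random_partition(rng: np.random.Generator, n: int) -> Partition:
    """Uniformly random block assignment over n objects."""
    n_blocks = int(rng.integers(1, n + 1))
    block_of = rng.integers(0, n_blocks, size=n)
    # re-index to drop empty blocks
    used, block_of = np.unique(block_of, return_inverse=True)
    blocks = [np.flatnonzero(block_of == b) for b in range(used.size)]
    return Partition(blocks=blocks, block_of=block_of)


def random_decision_table(rng: np.random.Generator, structured: bool = True) -> DecisionTable:
    """Small random decision table; structured mode derives the decision from
    a hidden attribute subset so that a genuine reduct exists."""
    n = int(rng.integers(8, 31))
    d = int(rng.integers(2, 9))
    vals = rng.integers(0, 3, size=(n, d))
    if structured:
        k = int(rng.integers(1, min(3, d) + 1))
        rel = rng.choice(d, size=k, replace=False)
        lut: dict[tuple, int] = {}
        dec = np.empty(n, dtype=int)
        for i in range(n):
            key = tuple(vals[i, rel])
            if key not in lut:
                lut[key] = int(rng.integers(0, 2))
            dec[i] = lut[key]
    else:
        dec = rng.integers(0, 2, size=n)
    return DecisionTable([f"a{j}" for j in range(d)], vals, dec)
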