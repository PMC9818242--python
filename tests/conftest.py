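import numpy as np
import pytest

from plbin import ContingencyTable, ExpressionMatrix


@pytest.fixture
def binary_table():
    """The worked binary table: LL=9, LH=2, HL=1, HH=8 (rows A, cols B)."""
    return ContingencyTable((0, 1), (0, 1), np.array([[9, 2], [1, 8]]))


@pytest.fixture
def small_expr():
    values = np.array(
        [
            [1.0, 2.0, 3.0, 4.0, 5.0],
            [5.0, 4.0, 3.0, 2.0, 1.0],
            [2.0, 2.0, 2.0, 2.0, 2.0],
        ]
    )
    return ExpressionMatrix(["A", "B", "C"], [f"s{i}" for i in range(5)], values)


def random_table(rng, max_count=20, shape=(3, 3)):
    """A random non-degenerate contingency table."""
    counts = rng.integers(0, max_count, size=shape)
    if counts.sum() == 0:
        counts[0, 0] = 1
    return ContingencyTable(
        (-1, 0, 1) if shape[0] == 3 else (0, 1),
        (-1, 0, 1) if shape[1] == 3 else (0, 1),
        counts,
    )
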