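import numpy as np
import pytest

from hdemg import GridLayout


@pytest.fixture
def default_layout() -> GridLayout:
    """The standard 8x4 grid with the upper-right electrode absent (31 valid)."""
    return GridLayout()


@pytest.fixture
def full_layout() -> GridLayout:
    """An 8x4 grid with no missing electrode (32 valid)."""
    return GridLayout(missing=frozenset())


@pytest.fixture
def tiny_layout() -> GridLayout:
    """A 3x2 grid (6 valid electrodes) for hand-checkable cases."""
    return GridLayout(n_rows=3, n_cols=2, missing=frozenset())


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
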