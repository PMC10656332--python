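import numpy as np
import pytest
from hypothesis import settings

import sparsecmm as sc

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture
def three_item_table():
    """130 respondents on three binary items; the running worked example."""
    return sc.fixtures.three_item_example()


@pytest.fixture
def sparse_two_pattern_table():
    """Three binary items with only patterns 100 and 110 observed (65 each)."""
    return sc.fixtures.two_pattern_sparse()


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_dense_table(rng, J=3, max_cat=2, min_count=1, max_count=30):
    """A small table with strictly positive counts in every cell."""
    cats = tuple(int(c) for c in rng.integers(2, max_cat + 1, size=J))
    L = int(np.prod(cats))
    counts = rng.integers(min_count, max_count, size=L)
    pairs = [(sc.index_to_pattern(i, cats), int(c)) for i, c in enumerate(counts)]
    return sc.build_table(pairs, cats=cats)
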