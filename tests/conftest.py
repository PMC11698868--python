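import io
import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest
import skbio

sys.path.insert(0, str(Path(__file__).parent))  # makes `oracles` importable

from alphadiv.feature_io import FeatureTable


def random_count_vector(rng, max_s=50, max_count=1000):
    """Random sparse count vector with deliberately boosted rare classes."""
    s = int(rng.integers(2, max_s + 1))
    counts = rng.integers(1, max_count + 1, size=s)
    mask = rng.random(s)
    counts[mask < 0.25] = 1
    counts[(mask >= 0.25) & (mask < 0.4)] = 2
    return counts


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def small_table():
    counts = pd.DataFrame(
        [[5, 1, 0, 2], [8, 1, 1, 0], [2, 2, 2, 2]],
        index=["s1", "s2", "s3"],
        columns=["A", "B", "C", "D"],
    )
    return FeatureTable(counts=counts)


@pytest.fixture
def four_tip_tree():
    return skbio.TreeNode.read(io.StringIO("((A:1,B:1):1,(C:1,D:1):1);"))
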