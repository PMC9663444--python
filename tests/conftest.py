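import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from mist.io_st import STData
from mist.synthetic_data import generate_synthetic_st
from mist.io_st import normalize_cpm


@pytest.fixture
def tiny_data():
    """4 spots x 3 genes, handcrafted."""
    counts = np.array(
        [
            [1.0, 1.0, 2.0],
            [0.0, 3.0, 1.0],
            [2.0, 0.0, 2.0],
            [5.0, 1.0, 0.0],
        ]
    )
    coords = np.array([[0, 0], [0, 1], [1, 0], [1, 1]])
    return STData(counts, coords, ["gA", "gB", "gC"], ["s0", "s1", "s2", "s3"])


@pytest.fixture(scope="session")
def quad_fixture():
    """20x20 quadrant fixture with 30% dropout (observed, truth)."""
    data, truth = generate_synthetic_st(
        20, 20, 200, n_regions=4, rank=3, dropout_rate=0.3, seed=0
    )
    return data, truth


@pytest.fixture(scope="session")
def quad_cpm(quad_fixture):
    data, truth = quad_fixture
    return normalize_cpm(data), truth
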