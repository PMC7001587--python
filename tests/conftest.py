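import numpy as np
import pytest

from sharedrep.info_analysis import BinnedResponseTable
from sharedrep.synthetic_data import GeneratorConfig

# the worked example's (category x bin) response counts: 4 categories
# A-D presented 100 times each, 3 activation bins
TABLE1_COUNTS = np.array([
    [3, 17, 80],
    [68, 31, 1],
    [73, 25, 2],
    [65, 12, 23],
])
TABLE1_EDGES = [0.0, 0.33, 0.67, 1.0]
TABLE1_BITS = {"A": 1.097, "B": 0.380, "C": 0.336, "D": 0.059}


@pytest.fixture
def table1() -> BinnedResponseTable:
    return BinnedResponseTable(counts=TABLE1_COUNTS.copy(),
                               bin_edges=TABLE1_EDGES,
                               categories=list("ABCD"))


@pytest.fixture
def tiny_config() -> GeneratorConfig:
    """A small but full-shape generator configuration for fast tests."""
    return GeneratorConfig(per_class_train=4, per_class_test=3,
                           audio_per_class=3, seed=7)


def brute_force_information(counts: np.ndarray, s_index: int) -> float:
    """Independent oracle: evaluate the information sum directly on an
    explicitly materialized joint probability table."""
    counts = np.asarray(counts, dtype=float)
    joint = counts / counts.sum()          # P(r, s) over the whole table
    p_s = joint.sum(axis=1)
    p_r = joint.sum(axis=0)
    total = 0.0
    for r in range(counts.shape[1]):
        p_r_given_s = joint[s_index, r] / p_s[s_index]
        if p_r_given_s > 0:
            total += p_r_given_s * np.log2(p_r_given_s / p_r[r])
    return total
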