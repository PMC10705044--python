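import numpy as np
import pandas as pd
import pytest

from granulefate.active_community import CountMatrix
from granulefate.synthetic_data import SimConfig, simulate_community


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    """A scaled-down but otherwise default study scenario."""
    return SimConfig(
        seed=101,
        n_zotus=40,
        depth_dna=4000,
        depth_cdna=4000,
        community_days=(0, 5, 17),
    )


@pytest.fixture(scope="session")
def community(small_config):
    return simulate_community(small_config)


@pytest.fixture()
def tiny_pair():
    """Hand-built paired matrices with one structural phantom (ZOTU d)."""
    dna = pd.DataFrame(
        {"s1": [60, 30, 10, 0], "s2": [40, 40, 20, 0]},
        index=["a", "b", "c", "d"],
    )
    cdna = pd.DataFrame(
        {"s1": [50, 20, 0, 30], "s2": [30, 30, 10, 30]},
        index=["a", "b", "c", "d"],
    )
    meta = pd.DataFrame(
        {"reactor": ["test", "test"], "day": [0, 5]}, index=["s1", "s2"]
    )
    return (
        CountMatrix(dna, "DNA", meta),
        CountMatrix(cdna, "cDNA", meta),
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
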