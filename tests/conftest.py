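import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from stygodiv import AbundanceTable, CommunityVector, generate_scenario

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture
def toy_community():
    """Counts (2, 1, 1): small enough for hand summation."""
    return CommunityVector(np.array(["a", "b", "c"]), np.array([2, 1, 1]))


def uniform_community(s: int, count: int = 10) -> CommunityVector:
    ids = np.array([f"sp{i:02d}" for i in range(s)], dtype=object)
    return CommunityVector(ids, np.full(s, count))


@pytest.fixture
def tiny_table():
    """3 species x 4 samples over 2 sites, one year; hand-checkable."""
    counts = pd.DataFrame(
        {
            "s1a": [1, 2, 3],
            "s1b": [4, 5, 6],
            "s2a": [0, 1, 2],
            "s2b": [2, 0, 4],
        },
        index=["a", "b", "c"],
    )
    guild = pd.Series(
        {"a": "stygobite", "b": "non_stygobite", "c": "stygobite"}
    )
    meta = pd.DataFrame(
        {
            "site": ["s1", "s1", "s2", "s2"],
            "year": [1997, 1997, 1997, 1997],
            "replicate": ["r1", "r2", "r1", "r2"],
        },
        index=["s1a", "s1b", "s2a", "s2b"],
    )
    return AbundanceTable(counts=counts, guild=guild, sample_meta=meta)


@pytest.fixture(scope="session")
def scenario_1997():
    return generate_scenario("1997", seed=11)


@pytest.fixture(scope="session")
def scenario_2005():
    return generate_scenario("2005", seed=12)


@pytest.fixture(scope="session")
def scenario_2012():
    return generate_scenario("2012", seed=13)
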