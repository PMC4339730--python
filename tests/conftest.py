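import numpy as np
import pytest

from minewebs.fixture import paper_fixture
from minewebs.simulate import SynthConfig, simulate_library


@pytest.fixture(scope="session")
def fixture_tables():
    """The deterministic in-study tables (records, assays, assignments)."""
    return paper_fixture()


@pytest.fixture(scope="session")
def small_library():
    """A 10-species barcode library with queries and ground truth."""
    cfg = SynthConfig(seed=42)
    refs, queries, truth = simulate_library(cfg)
    return cfg, refs, queries, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(20120613)
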