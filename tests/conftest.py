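import numpy as np
import pandas as pd
import pytest

from metarep.formats_io import ReadRecord
from metarep.synthetic import (
    SimCatalogSpec,
    SimCommunitySpec,
    simulate_abundances,
    simulate_catalog,
)


@pytest.fixture(scope="session")
def small_catalog() -> pd.DataFrame:
    """2,000-gene / 20-species catalog with the default bimodal GC mixture."""
    return simulate_catalog(SimCatalogSpec(n_genes=2000, n_species=20), seed=11)


@pytest.fixture(scope="session")
def small_profile(small_catalog) -> pd.Series:
    return simulate_abundances(small_catalog, SimCommunitySpec(), seed=12)


@pytest.fixture()
def uniform_read():
    def make(q: int, length: int = 100, read_id: str = "r") -> ReadRecord:
        return ReadRecord(read_id, "A" * length, np.full(length, q, dtype=np.int64))

    return make
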