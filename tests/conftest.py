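import numpy as np
import pandas as pd
import pytest

from hostvar import synthdata
from hostvar.types import PeakTable


@pytest.fixture
def tiny_peak_table() -> PeakTable:
    """Four plants, two populations, three compounds; hand-checkable."""
    idx = pd.Index(["p1", "p2", "p3", "p4"], name="plant")
    X = pd.DataFrame(
        [[2.0, 4.0, 0.0],
         [1.0, 1.0, 2.0],
         [3.0, 0.0, 6.0],
         [4.0, 0.0, 0.0]],
        index=idx, columns=["c1", "c2", "c3"],
    )
    return PeakTable(
        intensities=X,
        dry_mass=pd.Series([2.0, 1.0, 1.5, 1.0], index=idx),
        population=pd.Series(["A", "A", "B", "B"], index=idx),
        status=pd.Series(["colonized", "colonized", "uncolonized", "uncolonized"],
                         index=idx),
    )


@pytest.fixture
def default_peak_table():
    table, truth = synthdata.generate_peak_table(synthdata.SyntheticScenario(seed=42))
    return table, truth


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
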