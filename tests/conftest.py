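import numpy as np
import pandas as pd
import pytest

from dyadcomm import CountTable


def make_table(counts, genera=None, cohorts=None, niche="feces", dyads=None,
               prefix="S"):
    """Build a small CountTable from a list of count rows."""
    counts = np.asarray(counts)
    n, g = counts.shape
    genera = genera or [f"G{j}" for j in range(g)]
    ids = [f"{prefix}{i}" for i in range(n)]
    cohorts = cohorts or ["A"] * n
    dyads = dyads if dyads is not None else [f"d{i}" for i in range(n)]
    meta = pd.DataFrame(
        {"cohort": cohorts, "dyad_id": dyads, "niche": [niche] * n}, index=ids
    )
    return CountTable(pd.DataFrame(counts, index=ids, columns=genera), meta)


@pytest.fixture
def toy_table():
    return make_table([[5, 5], [10, 0], [0, 1]])


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)
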