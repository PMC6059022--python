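import numpy as np
import pandas as pd
import pytest

from dimertarget.catalog import load_catalog, load_pairing_rules
from dimertarget.diffexpr import CountMatrix


@pytest.fixture(scope="session")
def catalog():
    return load_catalog()


@pytest.fixture(scope="session")
def rules(catalog):
    return load_pairing_rules(catalog=catalog)


@pytest.fixture()
def small_counts():
    """Deterministic 6-gene x 6-sample count matrix, 3 tumor / 3 normal."""
    rng = np.random.default_rng(7)
    counts = pd.DataFrame(
        rng.poisson(100, size=(6, 6)),
        index=[f"G{i}" for i in range(6)],
        columns=[f"S{i}" for i in range(6)],
    )
    cond = pd.Series(
        ["tumor"] * 3 + ["normal"] * 3, index=counts.columns, name="condition"
    )
    return CountMatrix(counts=counts, condition=cond)
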