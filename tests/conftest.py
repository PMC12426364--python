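import numpy as np
import pandas as pd
import pytest

from dutycast import GeneratorSpec, ReceiptsTable, generate, scenario
from dutycast.data_io import parse_month


def make_table(values, start="2010-01", categories=("beer", "cider", "spirits", "wine"),
               basis="deflated(2025-01)"):
    """Build a ReceiptsTable from an (n_months, D) array."""
    values = np.asarray(values, dtype=float)
    months = pd.period_range(parse_month(start), periods=values.shape[0], freq="M")
    return ReceiptsTable(
        pd.DataFrame(values, index=months, columns=list(categories)), basis=basis
    )


@pytest.fixture(scope="session")
def null_panel():
    """One noisy shock-free panel at the default study conditions."""
    return generate(scenario("null", seed=42))


@pytest.fixture(scope="session")
def noiseless_spec():
    return GeneratorSpec(seed=0, noise_sd=np.zeros(4))


@pytest.fixture(scope="session")
def noiseless_panel(noiseless_spec):
    return generate(noiseless_spec)
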