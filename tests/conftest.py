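import numpy as np
import pytest

from pamtox import (
    AssayScenario,
    MixtureSpec,
    Truth4PL,
    default_scenario,
    geometric_dose_series,
)
from pamtox.datasets import toxic_unit_table


@pytest.fixture(scope="session")
def tu_table_24h():
    return toxic_unit_table(24.0)


@pytest.fixture(scope="session")
def demo_scenario():
    return default_scenario(seed=12345)


@pytest.fixture(scope="session")
def diuron_truth():
    return Truth4PL(bottom=0.0, top=100.0, hill=1.0, ic50=4.3)


@pytest.fixture()
def noiseless_curve():
    """Exact 4PL observations (B=0, T=100, h=1.5, IC50=10) at 7 doses x 3 reps."""
    truth = Truth4PL(0.0, 100.0, 1.5, 10.0)
    doses = geometric_dose_series(10.0)
    rows = np.array([[d, truth.inhibition(d)] for d in doses for _ in range(3)])
    return truth, rows


@pytest.fixture(scope="session")
def binary_mixture_spec():
    return MixtureSpec.equal_proportions("diuron+atrazine", ["diuron", "atrazine"])
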