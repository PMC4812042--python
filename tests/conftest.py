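import matplotlib

matplotlib.use("Agg")

import numpy as np
import pytest

from qprototype import ConceptDisjunctionHilbert, GaussianPair
from qprototype.datasets import load_fruits_vegetables, load_wavefield_solution
from qprototype.membership import MembershipRecord, MembershipTable


@pytest.fixture(scope="session")
def table1():
    return load_fruits_vegetables()


@pytest.fixture(scope="session")
def fitted(table1):
    return ConceptDisjunctionHilbert().fit(table1)


@pytest.fixture(scope="session")
def wavesol():
    return load_wavefield_solution()


@pytest.fixture(scope="session")
def pair():
    return GaussianPair.published()


@pytest.fixture(scope="session")
def exact_table(table1):
    """Reference table with each probability column rescaled to sum exactly to one."""
    mu_A = table1.mu_A / table1.mu_A.sum()
    mu_B = table1.mu_B / table1.mu_B.sum()
    mu_D = table1.mu_AorB / table1.mu_AorB.sum()
    records = [
        MembershipRecord(item, float(a), float(b), float(d))
        for item, a, b, d in zip(table1.items, mu_A, mu_B, mu_D)
    ]
    return MembershipTable(records, normalized=True)


@pytest.fixture
def rng():
    return np.random.default_rng(20240101)
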