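import numpy as np
import pytest

from cdta import (
    ItemParameters,
    QMatrix,
    class_probability_table,
    enumerate_latent_classes,
)
from cdta.sim_eval import generate_item_bank


@pytest.fixture(scope="session")
def space_k2():
    return enumerate_latent_classes(2)


@pytest.fixture(scope="session")
def space_k3():
    return enumerate_latent_classes(3)


@pytest.fixture(scope="session")
def space_k4():
    return enumerate_latent_classes(4)


@pytest.fixture
def dina_bank_k2():
    """Small deterministic DINA bank: 3 items over 2 attributes."""
    q = QMatrix([[1, 0], [1, 1], [0, 1]])
    params = ItemParameters(model="DINA", slip=[0.1, 0.1, 0.1], guess=[0.2, 0.2, 0.2])
    return q, params


def random_bank(seed, M=6, K=2, model="DINA"):
    return generate_item_bank(M, K, model, np.random.default_rng(seed))


@pytest.fixture
def table_k2(dina_bank_k2, space_k2):
    q, params = dina_bank_k2
    return class_probability_table(q, params, space_k2)
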