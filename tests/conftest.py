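import numpy as np
import pytest

from haemodesk import synth
from haemodesk.store import Actor, ClinicalStore, counter_clock


@pytest.fixture
def physician():
    return Actor("dr-a", "physician")


@pytest.fixture
def documentarist():
    return Actor("doc-b", "documentarist")


@pytest.fixture
def scientist():
    return Actor("sci-c", "scientist")


@pytest.fixture
def administrator():
    return Actor("adm-d", "administrator")


@pytest.fixture
def store():
    """In-memory store with the shipped core-data vocabulary installed."""
    s = ClinicalStore(seed=42, clock=counter_clock())
    synth.install_core_data(s)
    yield s
    s.close()


@pytest.fixture
def empty_store():
    s = ClinicalStore(seed=43, clock=counter_clock())
    yield s
    s.close()


@pytest.fixture(scope="session")
def small_cohort():
    """Seeded 2+2 synthetic cohort shared by read-only tests."""
    config = synth.CohortConfig(seed=1234, n_cml=2, n_nhl=2)
    store, key = synth.gen_cohort(config)
    return store, key


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
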