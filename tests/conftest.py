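import numpy as np
import pytest
from hypothesis import settings

from memppi.io_formats import TripleRecord
from memppi.synthetic import SimConfig, generate_dataset

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def small_sim():
    """A small generated study shared by read-only tests."""
    return generate_dataset(SimConfig(n_docs=30, dim=16, seed=3))


def make_rotation_kb(n_entities: int = 20, n_relations: int = 3):
    """A perfectly consistent toy KB: relation r maps e_i to e_{i+shift_r}.

    With 20 entities and 3 relations this yields 60 unique triples whose
    structure a translation model can exploit.
    """
    triples = []
    for r in range(n_relations):
        shift = r + 1
        for i in range(n_entities):
            triples.append(
                TripleRecord(f"e{i}", f"r{r}", f"e{(i + shift) % n_entities}")
            )
    return triples


@pytest.fixture(scope="session")
def rotation_kb():
    return make_rotation_kb()


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
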