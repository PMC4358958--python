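import numpy as np
import pytest

from mir30design import (
    SvmConfig,
    Transcript,
    enumerate_candidates,
    train,
)
from mir30design.synthetic import synthetic_records


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def transcript():
    """A 200-nt N-free transcript with a fixed seed."""
    r = np.random.default_rng(7)
    return Transcript("tx1", "".join(r.choice(list("ACGT"), size=200)))


@pytest.fixture(scope="session")
def candidates(transcript):
    return enumerate_candidates(transcript)


@pytest.fixture(scope="session")
def small_records():
    """300 synthetic training records with a planted signal (seed 0)."""
    records, truth = synthetic_records(300, seed=0)
    return records, truth


@pytest.fixture(scope="session")
def small_model(small_records):
    records, _ = small_records
    return train(records, SvmConfig(seed=0))


def random_seq(r, length, alphabet="ACGT"):
    return "".join(r.choice(list(alphabet), size=length))
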