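import numpy as np
import pytest

from nucfuse import SyntheticSpec, generate
from nucfuse.io_formats import CANONICAL_ALPHABET, SequenceRecord


@pytest.fixture(scope="session")
def small_dataset():
    """Default 3-class synthetic draw used across tests."""
    return generate(SyntheticSpec(seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_record(rng, L, rec_id="r"):
    letters = np.array(list(CANONICAL_ALPHABET))
    return SequenceRecord(id=rec_id, sequence="".join(letters[rng.integers(0, 20, L)]))
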