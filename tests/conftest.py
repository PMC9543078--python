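import numpy as np
import pytest

from mitokin import CircularReference, bundled_reference


@pytest.fixture(scope="session")
def ref():
    """The bundled synthetic 16,569-base reference with default masking."""
    return bundled_reference()


def make_homopolymer_rich(length: int, seed: int, masked=()):
    """Short random reference with long homopolymer runs, for indel tests."""
    rng = np.random.default_rng(seed)
    seq = []
    while len(seq) < length:
        base = str(rng.choice(list("ACGT")))
        seq.extend(base * int(rng.integers(1, 7)))
    return CircularReference("hp", "".join(seq[:length]), masked_ranges=masked)


@pytest.fixture(scope="session")
def small_ref():
    """200-base homopolymer-rich reference with one masked interval."""
    return make_homopolymer_rich(200, seed=7, masked=((50, 55),))
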