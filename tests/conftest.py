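import random

import pytest

from venomkit.codons import SENSE_CODONS


@pytest.fixture
def rng():
    return random.Random(20240917)


@pytest.fixture
def random_codon_seq(rng):
    """Factory for random stop-free coding sequences."""

    def make(n_codons: int) -> str:
        return "".join(rng.choice(SENSE_CODONS) for _ in range(n_codons))

    return make
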