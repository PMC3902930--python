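import numpy as np
import pytest

from nonbsplice.scan import ScanParams

ALPHABET = np.array(list("ACGT"))


def random_sequence(rng, length, probs=(0.25, 0.25, 0.25, 0.25)) -> str:
    """i.i.d. nucleotide string with the given A/C/G/T probabilities."""
    probs = np.asarray(probs, dtype=float)
    return "".join(ALPHABET[rng.choice(4, size=length, p=probs / probs.sum())])


@pytest.fixture
def params() -> ScanParams:
    return ScanParams()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20_130_515)
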