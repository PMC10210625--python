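import numpy as np
import pytest

from censcan.io_core import decode_codes
from censcan.synthetic_genome import random_codes


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def random_seq(n: int, rng: np.random.Generator, gc: float = 0.5) -> str:
    return decode_codes(random_codes(n, rng, gc=gc))


@pytest.fixture
def make_seq():
    return random_seq
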