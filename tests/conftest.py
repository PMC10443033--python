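import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for _oracles

from evolvrseq.simulate import make_default_amplicon


@pytest.fixture(scope="session")
def amplicon():
    """The default synthetic amplicon and its four guides."""
    reference, guides = make_default_amplicon()
    return reference, guides


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_seq(rng, length):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=length))
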