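import numpy as np
import pytest

from aglr import PenaltyConfig, parse_newick


@pytest.fixture
def std_config():
    """Penalties of the worked examples: gain 50, loss 30, Manhattan."""
    return PenaltyConfig(c1=50, c2=30, lam=1)


@pytest.fixture
def cherry():
    return parse_newick("(A,B);")


def make_rng(seed: int) -> np.random.Generator:
    return np.random.default_rng(seed)
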