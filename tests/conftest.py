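import numpy as np
import pytest

from numts.config import PipelineConfig
from numts.f84 import F84Params
from numts.tree import drosophila_tree


@pytest.fixture
def rng():
    return np.random.default_rng(20120307)


@pytest.fixture
def cfg():
    return PipelineConfig()


@pytest.fixture(scope="session")
def dros_tree():
    return drosophila_tree()


@pytest.fixture(scope="session")
def dros_tree_outgroup():
    return drosophila_tree(with_outgroup=True)


@pytest.fixture
def at_rich_model():
    return F84Params(freqs=np.array([0.39, 0.11, 0.11, 0.39]), ts_tv_ratio=2.0)


def random_dna(rng, n, at=0.58):
    p = [at / 2, (1 - at) / 2, (1 - at) / 2, at / 2]
    return "".join(rng.choice(list("ACGT"), size=n, p=p))


@pytest.fixture
def make_dna():
    return random_dna
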