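import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_probmap(rng, h=8, w=8):
    """A valid 2-channel probability map of the given size."""
    from pointseg.network import ProbMap
    from pointseg.autodiff import Tensor

    logits = rng.standard_normal((2, h, w))
    e = np.exp(logits - logits.max(axis=0, keepdims=True))
    return ProbMap(Tensor(e / e.sum(axis=0, keepdims=True)))


@pytest.fixture
def probmap_factory(rng):
    return lambda h=8, w=8: random_probmap(rng, h, w)
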