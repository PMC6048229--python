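import numpy as np
import pytest

from gwcausal import DiscreteSample, DomainSpec


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


def make_sample(x, y, xm=3, ym=2, x_mode="cyclic", y_mode="cyclic"):
    return DiscreteSample(np.asarray(x), np.asarray(y),
                          DomainSpec(x_mode, xm), DomainSpec(y_mode, ym))


@pytest.fixture
def geno_sample():
    """Small deterministic genotype-trait sample."""
    x = np.array([0, 0, 0, 1, 1, 2, 0, 1, 2, 2] * 30)
    y = np.array([0, 1, 0, 1, 0, 1, 0, 0, 1, 1] * 30)
    return make_sample(x, y)
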