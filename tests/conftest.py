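import numpy as np
import pytest

from optimdase import (
    AttcSimConfig,
    SequenceEncoder,
    TfbsSimConfig,
    simulate_attc,
    simulate_tfbs,
)


@pytest.fixture(scope="session")
def small_tfbs():
    """120 labelled 14-bp sequences with a planted GC-box motif."""
    return simulate_tfbs(TfbsSimConfig(n_positive=60, n_negative=60, seed=7))


@pytest.fixture(scope="session")
def encoded_tfbs(small_tfbs):
    enc = SequenceEncoder(window=3).fit(small_tfbs.sequences)
    X = enc.transform(small_tfbs.sequences)
    return X, small_tfbs.labels, enc


@pytest.fixture(scope="session")
def small_attc():
    """300-row feature table: 30 features, 2 low-variance, 3 informative."""
    return simulate_attc(
        AttcSimConfig(n_samples=300, n_features=30, n_low_variance=2,
                      n_informative=3, seed=11)
    )


@pytest.fixture
def rng():
    return np.random.RandomState(1234)
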