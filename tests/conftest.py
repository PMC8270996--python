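import numpy as np
import pytest

from clops.network import ClassifierSpec
from clops.signal_data import DEFAULT_CLASS_PALETTE, SyntheticConfig, make_stream


@pytest.fixture(scope="session")
def tiny_config():
    """Very small generator settings for structural tests (not the study runs)."""
    return SyntheticConfig(
        n_classes=4, L=200, fs=50.0, n_train=6, n_val=4, n_test=4, seed=0,
        segments_per_patient=2,
    )


@pytest.fixture(scope="session")
def tiny_stream(tiny_config):
    return make_stream("class_il", tiny_config)


@pytest.fixture(scope="session")
def tiny_spec():
    return ClassifierSpec(channels=(4, 8), kernels=(5, 5), pool=4, dropout=0.3)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def random_posterior(rng, M, T, C):
    """Random M×T×C simplex tensor."""
    G = rng.gamma(1.0, size=(M, T, C))
    return G / G.sum(axis=-1, keepdims=True)
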