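import numpy as np
import pytest

from fetseg import PhantomParams, generate_dataset


@pytest.fixture(scope="session")
def phantom_set():
    """Ten 64x64 phantoms, 20% of them first-trimester-like (no CSP/LV)."""
    return generate_dataset(10, PhantomParams(height=64, width=64, seed=11))


@pytest.fixture(scope="session")
def small_phantoms():
    """Three 48x48 phantoms for quick geometric checks."""
    return generate_dataset(3, PhantomParams(height=48, width=48, seed=5), no_structures_frac=0.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_label_map(rng, shape=(8, 8), n_classes=4):
    return rng.integers(0, n_classes, size=shape)
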