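import numpy as np
import pandas as pd
import pytest

from pkmt.synthdata import SynthConfig, generate_pk_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """500-compound synthetic table shared across tests (read-only)."""
    return generate_pk_dataset(SynthConfig(n_compounds=500, seed=11))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture()
def toy_regression(rng):
    """60/20 train/val toy with one informative feature out of four."""
    X = rng.normal(size=(80, 4))
    y = 2.0 * X[:, 0] + 0.3 * rng.normal(size=80)
    return (X[:60], y[:60], X[60:], y[60:])
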