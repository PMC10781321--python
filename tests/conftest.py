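"""Shared fixtures.

The expensive artifacts (the default 200-record dataset and the autoencoder
trained on it) are session-scoped and shared between the module tests and
the acceptance suite.
"""

from __future__ import annotations

import numpy as np
import pytest

from fogbci.autoencoder import TrainConfig, train_autoencoder
from fogbci.preprocessing import preprocess_dataset
from fogbci.synthetic import SyntheticSpec, generate_dataset

#: Seed of the reference synthetic dataset used by the end-to-end checks.
DATASET_SEED = 7


@pytest.fixture(scope="session")
def default_dataset():
    """The reference synthetic dataset: 200 records, 256 Hz, 2 s, separation 2."""
    spec = SyntheticSpec(n_records=200, separation=2.0, seed=DATASET_SEED)
    return generate_dataset(spec)


@pytest.fixture(scope="session")
def preprocessed_dataset(default_dataset):
    return preprocess_dataset(default_dataset)


@pytest.fixture(scope="session")
def trained_autoencoder(preprocessed_dataset):
    """Autoencoder trained with the default 30-epoch configuration."""
    encoder, decoder, history = train_autoencoder(
        preprocessed_dataset, TrainConfig(epochs=30, batch_size=16, seed=0)
    )
    return encoder, decoder, history


@pytest.fixture(scope="session")
def small_dataset():
    """A light dataset for unit-level checks: 48 records, 0.6 s."""
    spec = SyntheticSpec(n_records=48, duration=0.6, separation=2.0, seed=11)
    return generate_dataset(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
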