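"""Shared fixtures: the desk-scale dataset, trained AAE and toy black box.

The progressive AAE is trained once per session (about four minutes on
one CPU) and shared by the end-to-end and acceptance tests.
"""

import numpy as np
import pytest

from latexpl import (AdversarialAutoencoder, generate_dataset,
                     train_toy_blackbox)

# Desk-scale study conditions (see docs/methods.md)
DESK_SEED = 7
DESK_AAE = dict(latent_dim=32, stage_resolutions=(7, 14, 28),
                disc_widths=(64, 96, 128), epochs_per_stage=(8, 6, 6),
                batch_size=32, base_channels=32, mb_kernels=8, mb_dims=4)


@pytest.fixture(scope="session")
def dataset():
    """600 training images: 3 classes x 200, 28x28."""
    return generate_dataset(n_per_class=200, n_classes=3, resolution=28,
                            seed=11)


@pytest.fixture(scope="session")
def heldout():
    """Fresh draw from the same generator, disjoint by seed."""
    return generate_dataset(n_per_class=50, n_classes=3, resolution=28,
                            seed=99)


@pytest.fixture(scope="session")
def toy_bb(dataset):
    return train_toy_blackbox(dataset, seed=11)


@pytest.fixture(scope="session")
def desk_model(dataset):
    """3-stage progressive AAE trained on the desk-scale dataset."""
    model = AdversarialAutoencoder(random_state=DESK_SEED, **DESK_AAE)
    model.fit(dataset.images)
    return model


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
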