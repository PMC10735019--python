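"""Shared fixtures: hand-made shapes and a small synthetic study.

The session-scoped synthetic dataset is generated once on reduced
frames (320x416 px, track density scaled with frame area) and shared by
the classifier, workflow and end-to-end tests to keep the suite fast.
"""

from __future__ import annotations

import numpy as np
import pytest

from trackqc import classifiers, dataset, simulate, workflow
from trackqc.objects import TrackObject

SMALL_SHAPE = (320, 416)


def disk_coords(radius: int, center=(0, 0)) -> np.ndarray:
    """Lattice points with dx^2+dy^2 <= r^2 around a center."""
    r = int(np.ceil(radius))
    dy, dx = np.mgrid[-r : r + 1, -r : r + 1]
    sel = dx * dx + dy * dy <= radius * radius
    return np.stack([dy[sel] + center[0], dx[sel] + center[1]], axis=1)


def make_object(coords, intensities=None) -> TrackObject:
    coords = np.asarray(coords)
    if intensities is None:
        intensities = np.full(len(coords), 100.0)
    return TrackObject(coords, intensities)


@pytest.fixture
def disk3():
    return make_object(disk_coords(3, center=(10, 10)))


@pytest.fixture
def rect3x9():
    rr, cc = np.mgrid[0:3, 0:9]
    return make_object(np.stack([rr.ravel() + 5, cc.ravel() + 5], axis=1))


@pytest.fixture(scope="session")
def synthetic_images():
    """120 small frames, half adequate, fixed seed."""
    return simulate.generate_dataset(120, fraction_adequate=0.5, rng_seed=20240, shape=SMALL_SHAPE)


@pytest.fixture(scope="session")
def synthetic_table(synthetic_images):
    return workflow.features_from_images(synthetic_images)


@pytest.fixture(scope="session")
def synthetic_splits(synthetic_table):
    balanced = dataset.balance_classes(synthetic_table, rng_seed=7)
    return dataset.split(balanced, rng_seed=8)


@pytest.fixture(scope="session")
def nn_bundle(synthetic_splits):
    train_t, val_t, _ = synthetic_splits
    return workflow.train_bundle(
        train_t,
        val_t,
        model="nn",
        nn_config=classifiers.NNConfig(max_epochs=150, rng_seed=11),
    )
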