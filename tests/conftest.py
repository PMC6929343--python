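import numpy as np
import pytest

from anchor3d.anchor_shapes import Outline2D, generate_exemplar
from anchor3d.augmentation import generate_dataset


@pytest.fixture(scope="session")
def exemplars():
    """One deterministic exemplar outline per shape category."""
    return {c: generate_exemplar(c, 0) for c in range(1, 9)}


@pytest.fixture(scope="session")
def small_dataset():
    """A balanced 80-record synthetic dataset (10 per category)."""
    return generate_dataset(80, seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def records_to_matrices(records):
    X = np.stack([np.asarray(r.pixels) for r in records])
    Y = np.empty((len(records), 68))
    for i, r in enumerate(records):
        Y[i, 0::2] = r.coordinate_x
        Y[i, 1::2] = r.coordinate_y
    return X, Y
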