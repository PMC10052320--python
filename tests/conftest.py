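import numpy as np
import pytest

from feddis import (
    ClientDataset,
    PartitionSpec,
    build_vae,
    make_image_dataset,
    partition_by_proportions,
)

# severe label-skew proportions used across tests: each client dominated by
# one class (80/10/10 vs 10/10/80)
CASE2 = np.array([[0.1, 0.1, 0.8], [0.8, 0.1, 0.1]])


@pytest.fixture(scope="session")
def small_dataset():
    """2-class 32x32 fixture small enough for fast unit tests."""
    return make_image_dataset(n_classes=2, n_per_class=60,
                              n_test_per_class=20, seed=7)


@pytest.fixture(scope="session")
def skewed_shards(small_dataset):
    spec = PartitionSpec(mode="proportions", proportions=CASE2, seed=7)
    return partition_by_proportions(
        small_dataset.train_images, small_dataset.train_labels, spec)


@pytest.fixture(scope="session")
def tiny_vae():
    """Untrained but fully functional VAE for shape/plumbing tests."""
    return build_vae((1, 32, 32), d=8, widths=(4, 8), seed=3)


def shard_from_labels(labels, client_id=0, seed=0):
    """ClientDataset with 1-pixel dummy images, for label-only operations."""
    labels = np.asarray(labels, dtype=int)
    return ClientDataset(client_id=client_id,
                         images=np.zeros((len(labels), 1, 1, 1)),
                         labels=labels)
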