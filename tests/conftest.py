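import numpy as np
import pytest

from sdksmote.synthetic_data import (
    BlobSpec, isolation_spec, make_imbalanced_blobs,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def blob_dataset():
    """Standard overlapping two-blob fixture (E = 0.25, no isolates)."""
    ds, _ = make_imbalanced_blobs(BlobSpec(seed=7))
    return ds


@pytest.fixture
def separated_dataset_with_isolates():
    """Well-separated blobs with 3 planted isolates plus ground truth."""
    return make_imbalanced_blobs(isolation_spec(3, seed=11))


def brute_force_knn(points, query, k, exclude=None):
    """Independent k-NN oracle: full distance sort, ties by index."""
    d = np.sqrt(((np.asarray(points, float) - np.asarray(query, float)) ** 2)
                .sum(axis=1))
    idx = sorted(range(len(d)), key=lambda i: (d[i], i))
    if exclude is not None:
        idx = [i for i in idx if i != exclude]
    return idx[:k]
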