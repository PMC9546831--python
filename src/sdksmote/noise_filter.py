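"""Isolated-point pre-filter for the minority class.

A minority sample whose k nearest neighbours — searched over the *whole*
dataset, both classes — are all majority-class is treated as noise and
removed before any synthesis.  Interpolating from such a point would plant
synthetic minority samples deep inside majority territory and blur the class
boundary, which is exactly what the filter prevents.

Decisions are made in a single pass against the original dataset: removing
one outlier never changes the verdict on another (no cascade), so the result
is independent of sample ordering.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .data_model import LabeledDataset

__all__ = ["NoiseFilterResult", "knn_indices", "filter_isolated"]


@dataclass(frozen=True)
class NoiseFilterResult:
    """Partition of the minority index set into kept points and outliers."""

    kept_minority_indices: np.ndarray
    outlier_indices: np.ndarray
    k_used: int

    @property
    def l_outlier(self) -> int:
        return int(self.outlier_indices.shape[0])


def knn_indices(reference_points, query_point, k, *, self_index=None):
    """Indices of the ``k`` reference points nearest to ``query_point``.

    Euclidean distance; ties broken by ascending index.  When the query is a
    member of the reference set it is excluded from its own neighbourhood:
    pass its row as ``self_index``, or leave ``None`` to auto-exclude the
    first reference row exactly equal to the query.
    """
    R = np.asarray(reference_points, dtype=float)
    q = np.asarray(query_point, dtype=float).ravel()
    d = cdist(R, q[None, :]).ravel()
    if self_index is None:
        matches = np.flatnonzero((R == q).all(axis=1))
        if matches.size:
            self_index = int(matches[0])
    available = R.shape[0] - (1 if self_index is not None else 0)
    if k > available:
        raise ValueError(f"k too large: k={k} with {available} available points")
    if self_index is not None:
        d[self_index] = np.inf
    # stable sort on distance => ties resolved by ascending index
    order = np.argsort(d, kind="stable")
    return order[:k].copy()


def filter_isolated(dataset: LabeledDataset, k: int = 5) -> NoiseFilterResult:
    """Flag minority samples whose entire k-neighbourhood is majority-class.

    The neighbourhood of each minority point is searched among ALL samples
    (excluding itself).  Only minority samples are ever removed; majority
    samples pass through untouched.
    """
    if k < 1:
        raise ValueError("k must be a positive integer")
    n = dataset.n_samples
    if k >= n:
        raise ValueError(f"k too large: k={k} with {n} total samples")

    min_idx = dataset.minority_indices
    X = dataset.features
    D = cdist(X[min_idx], X)
    D[np.arange(min_idx.size), min_idx] = np.inf  # self-exclusion
    order = np.argsort(D, axis=1, kind="stable")[:, :k]
    neighbor_is_majority = dataset.majority_mask[order]
    isolated = neighbor_is_majority.all(axis=1)

    return NoiseFilterResult(
        kept_minority_indices=min_idx[~isolated],
        outlier_indices=min_idx[isolated],
        k_used=int(k),
    )
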