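"""Synthetic fixtures: Gaussian-blob imbalanced datasets and printed-table shapes.

``make_imbalanced_blobs`` produces the layout the oversampler assumes: a
majority blob, two (by default) minority sub-clusters, and optionally a few
*isolated* minority points planted inside the majority region — far enough
from every regular minority sample that a k-NN filter must flag them.  It
returns ground truth (which points are isolated, which sub-cluster each
regular minority point came from) so filtering and clustering can be scored
exactly.

``make_table3_shape`` returns the published per-dataset constants (class
counts, sub-cluster sizes, centre distances, weights) of the seven benchmark
datasets as a frozen record, for arithmetic fixtures — never generated data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .data_model import LabeledDataset, validate_dataset
from .cluster_weighting import as_rng

__all__ = ["BlobSpec", "BlobGroundTruth", "make_imbalanced_blobs",
           "isolation_spec", "make_table3_shape", "TABLE_DATASET_NAMES"]


@dataclass(frozen=True)
class BlobSpec:
    """Two-class Gaussian blob layout.

    Defaults give a 2-D dataset with one majority blob of 160 points at the
    origin and two minority sub-clusters of 20 points each at (-3, 0) and
    (3, 0), spread 1.5 — balance rate E = 40/160 = 0.25, with enough class
    overlap that imbalance actually hurts a classifier.  ``n_isolated``
    minority points (default 0) are planted near the majority centre, at
    least ``isolation_margin * spread`` away from every regular minority
    sample.
    """

    n_minority: int = 40
    n_majority: int = 160
    minority_centers: tuple = ((-3.0, 0.0), (3.0, 0.0))
    majority_centers: tuple = ((0.0, 0.0),)
    spread: float = 1.5
    n_isolated: int = 0
    isolation_margin: float = 3.0
    n_features: int = 2
    seed: int = 0


@dataclass(frozen=True)
class BlobGroundTruth:
    isolated_indices: np.ndarray       # dataset row indices of planted isolates
    minority_cluster_ids: np.ndarray   # per minority row; -1 for isolates
    minority_indices: np.ndarray


def _draw_blobs(rng, n, centers, spread, n_features):
    centers = np.asarray(centers, dtype=float)
    if centers.shape[1] != n_features:
        raise ValueError("spec infeasible: center dimension != n_features")
    per = np.full(len(centers), n // len(centers))
    per[: n % len(centers)] += 1
    pts, ids = [], []
    for ci, (c, cnt) in enumerate(zip(centers, per)):
        pts.append(rng.normal(c, spread, size=(cnt, n_features)))
        ids.append(np.full(cnt, ci))
    return np.vstack(pts), np.concatenate(ids)


def make_imbalanced_blobs(spec: BlobSpec):
    """Generate the dataset and its ground truth.

    Returns ``(LabeledDataset, BlobGroundTruth)``.  Labels are "min"/"maj"
    with "min" the declared minority.  Raises "spec infeasible" when the
    planted isolates cannot keep the required margin from the minority blobs.
    """
    if spec.n_isolated > spec.n_minority:
        raise ValueError("spec infeasible: n_isolated > n_minority")
    if spec.spread <= 0:
        raise ValueError("spec infeasible: spread must be > 0")
    rng = as_rng(spec.seed)

    n_regular = spec.n_minority - spec.n_isolated
    Xmin, cluster_ids = _draw_blobs(rng, n_regular, spec.minority_centers,
                                    spec.spread, spec.n_features)
    Xmaj, _ = _draw_blobs(rng, spec.n_majority, spec.majority_centers,
                          spec.spread, spec.n_features)

    margin = spec.isolation_margin * spec.spread
    isolates = []
    maj_centre = np.asarray(spec.majority_centers, dtype=float).mean(axis=0)
    for _ in range(spec.n_isolated):
        for _attempt in range(200):
            # widen the jitter if early tight placements keep failing, but
            # never beyond one spread: isolates must stay inside the
            # majority region, not drift out to a feasible no-man's-land
            scale = min(0.3 + 0.01 * _attempt, 1.0) * spec.spread
            p = maj_centre + rng.normal(0.0, scale, size=spec.n_features)
            far_from_minority = cdist(p[None, :], Xmin).min() > margin
            # keep isolates out of each other's neighbourhoods too,
            # otherwise they would mutually mask the filter
            far_from_isolates = (not isolates or
                                 cdist(p[None, :], np.vstack(isolates)).min()
                                 > spec.spread)
            if far_from_minority and far_from_isolates:
                isolates.append(p)
                break
        else:
            raise ValueError(
                "spec infeasible: cannot place an isolated point at margin "
                f"{margin:g} from the minority blobs"
            )
    if isolates:
        Xmin_all = np.vstack([Xmin, np.vstack(isolates)])
        cluster_ids = np.concatenate(
            [cluster_ids, np.full(len(isolates), -1)])
    else:
        Xmin_all = Xmin

    X = np.vstack([Xmin_all, Xmaj])
    y = np.array(["min"] * Xmin_all.shape[0] + ["maj"] * Xmaj.shape[0],
                 dtype=object)
    ds = validate_dataset(X, y, "min")
    minority_indices = np.arange(Xmin_all.shape[0])
    isolated_indices = minority_indices[cluster_ids == -1]

    # re-verify the planted-isolation property post-hoc
    if isolated_indices.size:
        regular = Xmin_all[cluster_ids >= 0]
        gap = cdist(Xmin_all[cluster_ids == -1], regular).min()
        assert gap > margin, "planted isolation margin violated"

    return ds, BlobGroundTruth(isolated_indices=isolated_indices,
                               minority_cluster_ids=cluster_ids,
                               minority_indices=minority_indices)


def isolation_spec(n_isolated: int = 3, seed: int = 0, **overrides) -> BlobSpec:
    """A well-separated blob spec for planted-isolation studies.

    Minority blobs sit far from the majority region so that points planted
    at the majority centre are unambiguous isolates at the default margin.
    """
    params = dict(n_minority=40, n_majority=160,
                  minority_centers=((-8.0, 0.0), (8.0, 0.0)),
                  majority_centers=((0.0, 0.0),), spread=1.0,
                  n_isolated=n_isolated, seed=seed)
    params.update(overrides)
    return BlobSpec(**params)


@dataclass(frozen=True)
class Table3Shape:
    """Published constants for one benchmark dataset (counts and distances)."""

    name: str
    n_samples: int
    n_attributes: int
    l: int                       # minority count
    m: int                       # majority count
    cluster_sizes: tuple         # two sub-cluster sizes, K = 2
    d: tuple                     # centre-to-majority-centroid distances D1, D2
    w_printed: tuple             # published weights W1, W2
    equilibrium_rate_pct: float  # published E as a percentage
    # weights reproducible from d to 1e-4; False marks a published rounding slip
    w2_consistent: bool = True


_TABLE = {
    "Pima": Table3Shape("Pima", 768, 8, 268, 500, (182, 86),
                        (51.927, 196.66), (0.7911, 0.2089), 53.6),
    "Haberman": Table3Shape("Haberman", 306, 3, 81, 225, (26, 55),
                            (13.950, 6.923), (0.3317, 0.6683), 36.0),
    "E. coli": Table3Shape("E. coli", 336, 7, 35, 301, (16, 19),
                           (0.4430, 0.5340), (0.5466, 0.4536), 11.62,
                           w2_consistent=False),
    "Wine": Table3Shape("Wine", 178, 13, 48, 130, (24, 24),
                        (252.448, 68.206), (0.2127, 0.7873), 36.92),
    "Breastcancer": Table3Shape("Breastcancer", 699, 10, 241, 458, (108, 133),
                                (10.368, 16.137), (0.6088, 0.3912), 52.62),
    "SPECT heart": Table3Shape("SPECT heart", 267, 22, 55, 212, (15, 40),
                               (1.169, 1.462), (0.5556, 0.4444), 25.94),
    "SPECTF heart": Table3Shape("SPECTF heart", 267, 44, 55, 212, (38, 17),
                                (38.800, 40.324), (0.5096, 0.4904), 25.94),
}

TABLE_DATASET_NAMES = tuple(_TABLE)


def make_table3_shape(dataset_name: str) -> Table3Shape:
    """Look up the published counts/distances record for one dataset name."""
    try:
        return _TABLE[dataset_name]
    except KeyError:
        raise ValueError(
            f"unknown dataset name {dataset_name!r}; "
            f"known: {TABLE_DATASET_NAMES}"
        ) from None
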