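"""Synthetic minority sample generation and the full oversampling pipeline.

Each sub-cluster fills its quota by a seed-and-neighbour loop: seeds are
drawn without replacement within a pass; a seed with ``need`` samples left
to make interpolates once with each of its ``need`` nearest in-cluster
neighbours if its neighbourhood is large enough, otherwise once with each of
its k nearest neighbours before moving on.  Interpolation between a seed x
and neighbour x_k1 with a fresh gamma ~ U(0,1) is, in the method's native
form,

    x_new = x + gamma * (x - x_k1)          (mode="native")

which *extrapolates away from* the neighbour — the mirror image of the
classical SMOTE rule

    x_new = x + gamma * (x_k1 - x)          (mode="smote-standard")

Both are offered; the native form is the default and the discrepancy is
deliberate and documented rather than silently "fixed".
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .data_model import LabeledDataset, BalanceReport, balance_report
from .noise_filter import NoiseFilterResult, filter_isolated
from .cluster_weighting import (
    AllocationPlan,
    ClusterModel,
    as_rng,
    allocate_quotas,
    compute_l_add,
    kmeans_fit,
    majority_centroid,
    make_allocation_plan,
    select_k_by_sse,
)

__all__ = ["SyntheticSample", "OversampleResult", "synthesize_cluster",
           "oversample", "classic_smote"]

MODES = ("native", "smote-standard")


@dataclass(frozen=True)
class SyntheticSample:
    """One interpolated sample with full provenance."""

    vector: np.ndarray
    cluster_id: int
    seed_index: int      # index into the cluster's point list (or dataset, once mapped)
    neighbor_index: int
    gamma: float


@dataclass(frozen=True)
class OversampleResult:
    """Balanced output: surviving originals plus synthetics, with provenance."""

    balanced_dataset: LabeledDataset
    provenance: list
    report: BalanceReport
    r_counters: np.ndarray
    plan: AllocationPlan
    filter_result: NoiseFilterResult
    cluster_model: ClusterModel
    is_synthetic: np.ndarray = field(default=None)  # bool per output row

    @property
    def n_synthetic(self) -> int:
        return len(self.provenance)


def _interpolate(seed, neighbor, gamma, mode):
    if mode == "native":
        return seed + gamma * (seed - neighbor)
    if mode == "smote-standard":
        return seed + gamma * (neighbor - seed)
    raise ValueError(f"unknown mode {mode!r}; expected one of {MODES}")


def _neighbour_order(P: np.ndarray, i: int) -> np.ndarray:
    """In-cluster neighbours of point i, nearest first, ties by index."""
    d = cdist(P[i][None, :], P).ravel()
    d[i] = np.inf
    return np.argsort(d, kind="stable")[: P.shape[0] - 1]


def synthesize_cluster(cluster_points, quota, k_syn, rng, mode="native"):
    """Fill one cluster's quota of synthetic samples.

    Seeds are visited in a random order without replacement; each seed
    contributes interpolations with its nearest in-cluster neighbours
    (nearest first, ties by ascending index) until the quota n_i is filled.
    The effective neighbourhood size is min(k_syn, cluster size - 1).  If a
    full pass over all seeds leaves the quota unfilled, a fresh pass starts.
    Gamma is drawn fresh per synthetic sample.
    """
    P = np.asarray(cluster_points, dtype=float)
    n = P.shape[0]
    quota = int(quota)
    if quota < 0:
        raise ValueError("quota must be >= 0")
    if quota == 0:
        return []
    if n < 2:
        raise ValueError("cluster too small: need >= 2 points for a positive quota")
    if k_syn < 1:
        raise ValueError("k_syn must be a positive integer")
    rng = as_rng(rng)
    k_eff = min(int(k_syn), n - 1)

    out: list[SyntheticSample] = []
    r_i = 0
    while r_i < quota:
        for seed_idx in rng.permutation(n):
            need = quota - r_i
            if need == 0:
                break
            neighbours = _neighbour_order(P, int(seed_idx))
            take = neighbours[:need] if k_eff >= need else neighbours[:k_eff]
            for nb in take:
                gamma = float(rng.random())
                vec = _interpolate(P[seed_idx], P[nb], gamma, mode)
                out.append(SyntheticSample(vector=vec, cluster_id=-1,
                                           seed_index=int(seed_idx),
                                           neighbor_index=int(nb),
                                           gamma=gamma))
            r_i += len(take)
            if k_eff >= need:
                break
    return out


def _redistribute_singletons(quotas, sizes, weights):
    """Move quota away from clusters too small to interpolate within.

    Clusters with < 2 members cannot host seed/neighbour pairs; their quota
    is re-allocated over the viable clusters by renormalised weights.
    """
    quotas = np.asarray(quotas).copy()
    viable = np.asarray(sizes) >= 2
    if viable.all():
        return quotas
    stranded = int(quotas[~viable].sum())
    if stranded == 0:
        quotas[~viable] = 0
        return quotas
    if not viable.any():
        raise ValueError("cluster too small: no cluster has >= 2 members")
    warnings.warn(
        f"redistributing {stranded} synthetic samples away from "
        f"{int((~viable).sum())} singleton cluster(s)", stacklevel=2,
    )
    w = np.asarray(weights, dtype=float).copy()
    w[~viable] = 0.0
    w = w / w.sum()
    extra = allocate_quotas(w, stranded)
    quotas[~viable] = 0
    return quotas + extra


def oversample(dataset: LabeledDataset, target_E, *, k_noise: int = 5,
               k_syn: int = 5, n_clusters=2, rng=None, mode: str = "native",
               standardize: bool = False, allow_noop: bool = False,
               k_max: int = 8, drop_threshold: float = 0.5) -> OversampleResult:
    """Run the full pipeline: filter -> cluster -> weight -> quota -> interpolate.

    Parameters
    ----------
    target_E : float in (0, 1]
        Desired post-sampling balance rate E' = l'/m.
    n_clusters : int or "auto"
        Number of minority sub-clusters; "auto" picks K by the SSE elbow.
    mode : "native" | "smote-standard"
        Interpolation direction (see module docstring).
    standardize : bool
        Z-score features for all geometry (filtering, clustering, distances);
        synthetics are mapped back to the raw scale.

    Returns an :class:`OversampleResult` whose balanced dataset contains every
    original sample except the filtered minority outliers, in their original
    order, followed by the synthetics (labelled with the minority label).
    """
    if mode not in MODES:
        raise ValueError(f"unknown mode {mode!r}; expected one of {MODES}")
    rng = as_rng(rng)

    X = dataset.features
    if standardize:
        mu = X.mean(axis=0)
        sd = X.std(axis=0)
        sd[sd == 0] = 1.0
        Xw = (X - mu) / sd
    else:
        mu, sd = 0.0, 1.0
        Xw = X
    work = LabeledDataset(Xw, dataset.labels, dataset.minority_label,
                          dataset.feature_names)

    filt = filter_isolated(work, k=k_noise)
    kept = filt.kept_minority_indices
    if kept.size < 2:
        raise ValueError("too few minority samples survive the noise filter")
    P = Xw[kept]

    l, m = dataset.minority_count, dataset.majority_count
    if n_clusters == "auto":
        K, _ = select_k_by_sse(P, min(k_max, P.shape[0]), rng,
                               drop_threshold=drop_threshold)
    else:
        K = int(n_clusters)
    # cap K below the kept-minority count so that, by pigeonhole, at least
    # one cluster has >= 2 members and can host seed/neighbour interpolation
    K = max(1, min(K, P.shape[0] - 1))
    model = kmeans_fit(P, K, rng, n_init=10)

    centroid = majority_centroid(work)
    plan = make_allocation_plan(model, centroid, l, filt.l_outlier, m,
                                target_E, allow_noop=allow_noop)
    quotas = _redistribute_singletons(plan.quotas, model.cluster_sizes,
                                      plan.normalized_weights)

    synthetics: list[SyntheticSample] = []
    r_counters = np.zeros(model.K, dtype=int)
    for ci in range(model.K):
        members = model.members(ci)
        if quotas[ci] == 0:
            continue
        made = synthesize_cluster(P[members], quotas[ci], k_syn, rng, mode)
        for s in made:
            # map cluster-local indices back to original dataset rows
            synthetics.append(SyntheticSample(
                vector=s.vector * sd + mu if standardize else s.vector,
                cluster_id=ci,
                seed_index=int(kept[members[s.seed_index]]),
                neighbor_index=int(kept[members[s.neighbor_index]]),
                gamma=s.gamma,
            ))
        r_counters[ci] = len(made)

    keep_mask = np.ones(dataset.n_samples, dtype=bool)
    keep_mask[filt.outlier_indices] = False
    X_keep = X[keep_mask]
    y_keep = dataset.labels[keep_mask]
    if synthetics:
        X_new = np.vstack([s.vector for s in synthetics])
        X_out = np.vstack([X_keep, X_new])
        y_out = np.concatenate([
            y_keep,
            np.full(len(synthetics), dataset.minority_label, dtype=object),
        ])
    else:
        X_out, y_out = X_keep, y_keep
    balanced = LabeledDataset(X_out, y_out, dataset.minority_label,
                              dataset.feature_names)
    is_synth = np.zeros(X_out.shape[0], dtype=bool)
    is_synth[X_keep.shape[0]:] = True

    return OversampleResult(
        balanced_dataset=balanced,
        provenance=synthetics,
        report=balance_report(balanced),
        r_counters=r_counters,
        plan=plan,
        filter_result=filt,
        cluster_model=model,
        is_synthetic=is_synth,
    )


def classic_smote(dataset: LabeledDataset, target_E, *, k_syn: int = 5,
                  rng=None, allow_noop: bool = False) -> OversampleResult:
    """Classical SMOTE baseline.

    Repeats l_add times: pick a minority seed uniformly, pick one of its
    k_syn minority nearest neighbours uniformly, interpolate
    x_new = x + gamma * (x_k1 - x).  No filtering, no clustering.
    """
    rng = as_rng(rng)
    min_idx = dataset.minority_indices
    if min_idx.size < 2:
        raise ValueError("too few minority samples: need >= 2 for SMOTE")
    l, m = dataset.minority_count, dataset.majority_count
    l_add, l_prime = compute_l_add(l, 0, m, target_E, allow_noop=allow_noop)

    P = dataset.features[min_idx]
    k_eff = min(int(k_syn), P.shape[0] - 1)
    synthetics = []
    for _ in range(l_add):
        si = int(rng.integers(P.shape[0]))
        neighbours = _neighbour_order(P, si)[:k_eff]
        nb = int(neighbours[rng.integers(len(neighbours))])
        gamma = float(rng.random())
        vec = _interpolate(P[si], P[nb], gamma, "smote-standard")
        synthetics.append(SyntheticSample(vector=vec, cluster_id=0,
                                          seed_index=int(min_idx[si]),
                                          neighbor_index=int(min_idx[nb]),
                                          gamma=gamma))

    if synthetics:
        X_out = np.vstack([dataset.features,
                           np.vstack([s.vector for s in synthetics])])
        y_out = np.concatenate([
            dataset.labels,
            np.full(len(synthetics), dataset.minority_label, dtype=object),
        ])
    else:
        X_out, y_out = dataset.features, dataset.labels
    balanced = LabeledDataset(X_out, y_out, dataset.minority_label,
                              dataset.feature_names)
    is_synth = np.zeros(X_out.shape[0], dtype=bool)
    is_synth[dataset.n_samples:] = True

    dummy_filter = NoiseFilterResult(kept_minority_indices=min_idx,
                                     outlier_indices=np.array([], dtype=int),
                                     k_used=0)
    dummy_model = ClusterModel(K=1, assignments=np.zeros(min_idx.size, dtype=int),
                               centres=P.mean(axis=0, keepdims=True),
                               sse=float(((P - P.mean(axis=0)) ** 2).sum()))
    plan = AllocationPlan(l_add=l_add, l_prime=l_prime,
                          distances=np.array([0.0]),
                          raw_weights=np.array([0.0]),
                          normalized_weights=np.array([1.0]),
                          quotas=np.array([l_add]))
    return OversampleResult(balanced_dataset=balanced, provenance=synthetics,
                            report=balance_report(balanced),
                            r_counters=np.array([l_add]), plan=plan,
                            filter_result=dummy_filter,
                            cluster_model=dummy_model, is_synthetic=is_synth)
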