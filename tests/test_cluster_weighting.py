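import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from sdksmote import (
    allocate_quotas, cluster_distances, compute_l_add, compute_weights,
    kmeans_fit, kmeanspp_seed, majority_centroid, select_k_by_sse,
    validate_dataset,
)
from sdksmote.cluster_weighting import ClusterModel
from sdksmote.synthetic_data import make_table3_shape, TABLE_DATASET_NAMES


class TestMajorityCentroid:
    def test_midpoint_and_identity(self):
        ds = validate_dataset([[0, 0], [2, 0], [1, 5]],
                              ["M", "M", "m"], "m")
        assert majority_centroid(ds).tolist() == [1.0, 0.0]
        ds1 = validate_dataset([[3, 4], [1, 5]], ["M", "m"], "m")
        assert majority_centroid(ds1).tolist() == [3.0, 4.0]

    def test_matches_independent_summation(self, rng):
        X = rng.normal(size=(60, 4))
        y = ["m"] * 10 + ["M"] * 50
        ds = validate_dataset(X, y, "m")
        # independent loop oracle
        maj = X[10:]
        expected = [sum(maj[j][i] for j in range(50)) / 50 for i in range(4)]
        np.testing.assert_allclose(majority_centroid(ds), expected, atol=1e-12)


class TestKmeansPlusPlus:
    def test_k_equals_n_selects_every_point(self, rng):
        pts = rng.normal(size=(6, 2))
        centres = kmeanspp_seed(pts, 6, rng)
        got = {tuple(c) for c in centres}
        assert got == {tuple(p) for p in pts}

    def test_k1_is_uniform_choice(self, rng):
        pts = np.arange(10, dtype=float).reshape(-1, 1)
        picks = [kmeanspp_seed(pts, 1, rng)[0, 0] for _ in range(2000)]
        counts = np.bincount(np.array(picks, dtype=int), minlength=10)
        assert counts.min() > 130  # uniform => ~200 each

    def test_d2_weighting_prefers_the_far_pair(self, rng):
        # two pairs separated by 100: after the first draw, the second centre
        # lands in the other pair with probability ~ (2*100^2)/(2*100^2 + eps)
        pts = np.array([[0.0, 0], [0.5, 0], [100.0, 0], [100.5, 0]])
        cross = 0
        trials = 500
        for _ in range(trials):
            centres = kmeanspp_seed(pts, 2, rng)
            cross += (centres[:, 0].max() - centres[:, 0].min()) > 50
        assert cross / trials > 0.99

    def test_k_too_large(self, rng):
        with pytest.raises(ValueError, match="K too large"):
            kmeanspp_seed(np.zeros((3, 2)), 4, rng)


def brute_force_best_partition(X, K):
    """Exhaustive minimum-SSE partition for tiny n (the k-means optimum)."""
    n = X.shape[0]
    best_sse, best = np.inf, None
    for assign in itertools.product(range(K), repeat=n):
        if len(set(assign)) < K:
            continue
        a = np.array(assign)
        sse = 0.0
        for k in range(K):
            members = X[a == k]
            sse += ((members - members.mean(axis=0)) ** 2).sum()
        if sse < best_sse:
            best_sse, best = sse, a
    return best_sse, best


class TestKmeansFit:
    def test_recovers_separated_blobs_and_matches_exhaustive_optimum(self, rng):
        for trial in range(20):
            centres = np.array([[0.0, 0.0], [40.0, 0.0]])
            X = np.vstack([rng.normal(c, 1.0, size=(5, 2)) for c in centres])
            model = kmeans_fit(X, 2, rng, n_init=5)
            opt_sse, opt_assign = brute_force_best_partition(X, 2)
            assert model.sse == pytest.approx(opt_sse, rel=1e-9)
            # same partition up to label swap
            agreement = (model.assignments == opt_assign).mean()
            assert agreement in (0.0, 1.0)

    def test_k1_closed_form(self, rng):
        X = rng.normal(size=(30, 3))
        model = kmeans_fit(X, 1, rng)
        np.testing.assert_allclose(model.centres[0], X.mean(axis=0), atol=1e-12)
        assert model.sse == pytest.approx(((X - X.mean(axis=0)) ** 2).sum())

    def test_centres_are_member_means_and_sse_consistent(self, rng):
        X = rng.normal(size=(50, 2))
        model = kmeans_fit(X, 3, rng, n_init=3)
        sse = 0.0
        for i in range(3):
            members = X[model.assignments == i]
            assert members.size  # no empty clusters survive
            np.testing.assert_allclose(model.centres[i], members.mean(axis=0),
                                       atol=1e-9)
            sse += ((members - model.centres[i]) ** 2).sum()
        assert model.sse == pytest.approx(sse)

    def test_agrees_with_sklearn_on_separated_blobs(self, rng):
        from sklearn.cluster import KMeans
        X = np.vstack([rng.normal(c, 0.5, size=(20, 2))
                       for c in ([0, 0], [30, 0], [0, 30])])
        ours = kmeans_fit(X, 3, rng, n_init=10)
        ref = KMeans(n_clusters=3, n_init=10, random_state=0).fit(X)
        assert ours.sse == pytest.approx(ref.inertia_, rel=1e-6)


class TestSelectK:
    def test_two_blobs_give_k2(self, rng):
        X = np.vstack([rng.normal(c, 1.0, size=(20, 2))
                       for c in ([-10, 0], [10, 0])])
        K, curve = select_k_by_sse(X, 6, rng)
        assert K == 2
        assert len(curve) == 6
        assert all(curve[i] >= curve[i + 1] - 1e-9 for i in range(5))

    def test_structureless_points_give_k1(self, rng):
        X = rng.uniform(size=(60, 2))
        K, _ = select_k_by_sse(X, 6, rng)
        assert K == 1

    def test_too_few_points(self, rng):
        with pytest.raises(ValueError, match="too few points"):
            select_k_by_sse(np.zeros((1, 2)), 2, rng)


class TestClusterDistances:
    def test_closed_form_cases(self):
        model = ClusterModel(K=2, assignments=np.array([0, 1]),
                             centres=np.array([[0.0, 0.0], [3.0, 4.0]]),
                             sse=0.0)
        np.testing.assert_allclose(cluster_distances(model, [0.0, 0.0]),
                                   [0.0, 5.0])

    def test_matches_componentwise_formula(self, rng):
        centres = rng.normal(size=(4, 6))
        centroid = rng.normal(size=6)
        model = ClusterModel(K=4, assignments=np.arange(4), centres=centres,
                             sse=0.0)
        got = cluster_distances(model, centroid)
        exp = [np.sqrt(sum((centroid[j] - centres[i, j]) ** 2
                           for j in range(6))) for i in range(4)]
        np.testing.assert_allclose(got, exp, atol=1e-12)

    def test_dimension_mismatch(self):
        model = ClusterModel(K=1, assignments=np.array([0]),
                             centres=np.zeros((1, 3)), sse=0.0)
        with pytest.raises(ValueError, match="shape error"):
            cluster_distances(model, [0.0, 0.0])


class TestComputeWeights:
    @pytest.mark.parametrize("name", TABLE_DATASET_NAMES)
    def test_reproduces_published_weight_pairs(self, name):
        shape = make_table3_shape(name)
        _, norm = compute_weights(np.array(shape.d))
        assert norm[0] == pytest.approx(shape.w_printed[0], abs=1e-4)
        if shape.w2_consistent:
            assert norm[1] == pytest.approx(shape.w_printed[1], abs=1e-4)

    def test_closer_cluster_gets_strictly_larger_weight(self, rng):
        for _ in range(50):
            d = rng.uniform(0.1, 10, size=rng.integers(2, 6))
            _, w = compute_weights(d)
            order_d = np.argsort(d)
            assert np.all(np.diff(w[order_d]) <= 1e-12)
            # strict where distances strictly differ
            for i, j in itertools.combinations(range(len(d)), 2):
                if d[i] < d[j]:
                    assert w[i] > w[j]

    def test_normalization_and_degenerate_cases(self):
        _, w = compute_weights(np.array([3.0, 3.0, 3.0]))
        np.testing.assert_allclose(w, [1 / 3] * 3, atol=1e-12)
        _, w1 = compute_weights(np.array([7.5]))
        assert w1.tolist() == [1.0]
        _, w0 = compute_weights(np.array([0.0, 0.0]))
        np.testing.assert_allclose(w0, [0.5, 0.5])
        raw, norm = compute_weights(np.array([1.0, 2.0, 3.0]))
        assert raw.sum() == pytest.approx(2.0)  # K-1 before renormalisation
        assert norm.sum() == pytest.approx(1.0, abs=1e-12)

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError, match="invalid distance"):
            compute_weights(np.array([1.0, -0.1]))


class TestComputeLAdd:
    @pytest.mark.parametrize("l, m, target, exp_lp, exp_ladd", [
        (268, 500, 0.9, 450, 182),   # Pima: balanced total 950
        (81, 225, 0.9, 202, 121),    # Haberman: floor(202.5), total 427
        (268, 500, 0.7, 350, 82),    # float droop guard: 0.7*500
        (35, 301, 0.9, 270, 235),    # E. coli: total 571
    ])
    def test_published_balanced_sizes(self, l, m, target, exp_lp, exp_ladd):
        l_add, l_prime = compute_l_add(l, 0, m, target)
        assert l_prime == exp_lp
        assert l_add == exp_ladd

    def test_fixed_point_and_outlier_offset(self):
        l_add, _ = compute_l_add(50, 0, 100, 0.5)
        assert l_add == 0
        l_add2, _ = compute_l_add(50, 5, 100, 0.5)
        assert l_add2 == 5  # removed outliers must be replaced

    def test_target_below_current_balance(self):
        with pytest.raises(ValueError, match="target balance already met"):
            compute_l_add(90, 0, 100, 0.5)
        l_add, _ = compute_l_add(90, 0, 100, 0.5, allow_noop=True)
        assert l_add == 0

    def test_invalid_target(self):
        with pytest.raises(ValueError):
            compute_l_add(10, 0, 100, 0.0)
        with pytest.raises(ValueError):
            compute_l_add(10, 0, 100, 1.5)


class TestAllocateQuotas:
    def test_forced_tie_and_single_cluster(self):
        assert allocate_quotas(np.array([0.5, 0.5]), 7).tolist() == [4, 3]
        assert allocate_quotas(np.array([1.0]), 10).tolist() == [10]
        assert allocate_quotas(np.array([0.3, 0.7]), 0).tolist() == [0, 0]

    def test_largest_remainder_against_brute_force(self, rng):
        def oracle(w, total):
            base = np.floor(w * total).astype(int)
            rem = w * total - base
            order = sorted(range(len(w)), key=lambda i: (-rem[i], i))
            for i in order[: total - base.sum()]:
                base[i] += 1
            return base
        for _ in range(200):
            K = int(rng.integers(2, 6))
            w = rng.dirichlet(np.ones(K))
            got = allocate_quotas(w, 100)
            assert got.tolist() == oracle(w, 100).tolist()
            assert got.sum() == 100

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000), st.integers(1, 8), st.integers(0, 2**31 - 1))
    def test_conservation_property(self, l_add, K, seed):
        w = np.random.default_rng(seed).dirichlet(np.ones(K))
        q = allocate_quotas(w, l_add)
        assert int(q.sum()) == l_add
        assert (q >= 0).all()
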