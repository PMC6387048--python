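"""Pre-rejection, manifold k-means, normality-based model selection."""

import numpy as np
import pytest
import scipy.stats

from rpotatoes.cluster import (
    MIN_CLUSTER_SIZE,
    RiemannianKMeans,
    RiemannianPotatoes,
    combine_pvalues_stouffer,
    prereject_outliers,
    riemannian_kmeans,
    select_cluster_count,
)
from rpotatoes.geometry import geometric_mean, riemannian_distance

from .conftest import random_spd, random_spd_stack


def brute_force_prereject(covs):
    """Independent O(N^2) reimplementation of the pre-rejection rule."""
    N = len(covs)
    d = np.zeros(N)
    for i in range(N):
        d[i] = np.mean(
            [riemannian_distance(covs[i], covs[j]) for j in range(N) if j != i]
        )
    thr = d.mean()
    rejected = [i for i in range(N) if d[i] > thr]
    kept = [i for i in range(N) if not d[i] > thr]
    return kept, rejected, d


def diagonal_family(rng, count, log_scale, n=3, jitter=0.05):
    """SPD matrices clustered around diag(e^log_scale)."""
    return np.stack(
        [
            np.diag(np.exp(log_scale + jitter * rng.standard_normal(n)))
            for _ in range(count)
        ]
    )


def tangent_cluster(rng, count, log_scale, n=3, mu_ln=-0.5, sd_ln=0.35):
    """SPD matrices at lognormal radii along random tangent directions from
    diag(e^log_scale): their distances to the center are exactly lognormal,
    the null of the normality-based selection rule."""
    from rpotatoes.geometry import _eig_fun

    M_half = np.diag(np.exp(np.asarray(log_scale, float) / 2.0))
    out = []
    for _ in range(count):
        Z = rng.standard_normal((n, n))
        U = (Z + Z.T) / 2
        U /= np.linalg.norm(U)
        r = rng.lognormal(mu_ln, sd_ln)
        out.append(M_half @ _eig_fun(r * U, np.exp) @ M_half)
    return np.stack(out)


class TestPrereject:
    def test_identical_matrices_all_kept(self):
        covs = np.stack([np.eye(3)] * 10)
        kept, rejected, d = prereject_outliers(covs)
        assert len(kept) == 10
        assert len(rejected) == 0
        np.testing.assert_allclose(d, 0.0)

    def test_far_outlier_rejected(self, rng):
        near = diagonal_family(rng, 9, np.zeros(3))
        far = np.diag(np.exp([10.0, 10.0, 10.0]))[None]
        covs = np.concatenate([near, far])
        kept, rejected, _ = prereject_outliers(covs)
        assert list(rejected) == [9]

    def test_matches_brute_force_on_random_sets(self, rng):
        for _ in range(10):
            covs = random_spd_stack(rng, int(rng.integers(5, 30)), 3)
            kept, rejected, d = prereject_outliers(covs)
            kept_o, rejected_o, d_o = brute_force_prereject(covs)
            assert list(kept) == kept_o
            assert list(rejected) == rejected_o
            np.testing.assert_allclose(d, d_o, rtol=1e-9)

    def test_partition_property(self, rng):
        covs = random_spd_stack(rng, 20, 4)
        kept, rejected, _ = prereject_outliers(covs)
        assert sorted(list(kept) + list(rejected)) == list(range(20))


class TestRiemannianKMeans:
    def test_k1_centroid_is_geometric_mean(self, rng):
        covs = random_spd_stack(rng, 12, 3)
        labels, centroids, inertia = riemannian_kmeans(covs, k=1, seed=0)
        np.testing.assert_array_equal(labels, 0)
        np.testing.assert_allclose(
            centroids[0], geometric_mean(covs).mean, rtol=1e-6
        )

    def test_two_separated_families_recovered(self, rng):
        a = diagonal_family(rng, 15, np.zeros(3))
        b = diagonal_family(rng, 15, np.full(3, 4.0))
        covs = np.concatenate([a, b])
        labels, _, _ = riemannian_kmeans(covs, k=2, seed=1)
        assert len(set(labels[:15])) == 1
        assert len(set(labels[15:])) == 1
        assert labels[0] != labels[15]

    def test_inertia_non_increasing(self, rng):
        covs = random_spd_stack(rng, 30, 3)
        km = RiemannianKMeans(n_clusters=3, random_state=2).fit(covs)
        hist = np.asarray(km.inertia_history_)
        assert np.all(np.diff(hist) <= 1e-9)

    def test_deterministic_given_seed(self, rng):
        covs = random_spd_stack(rng, 25, 3)
        km1 = RiemannianKMeans(n_clusters=3, random_state=42).fit(covs)
        km2 = RiemannianKMeans(n_clusters=3, random_state=42).fit(covs)
        np.testing.assert_array_equal(km1.labels_, km2.labels_)
        np.testing.assert_allclose(km1.cluster_centers_, km2.cluster_centers_)

    def test_k_exceeding_n_rejected(self, rng):
        with pytest.raises(ValueError):
            riemannian_kmeans(random_spd_stack(rng, 3, 3), k=5)

    def test_predict_assigns_nearest_centroid(self, rng):
        a = diagonal_family(rng, 10, np.zeros(3))
        b = diagonal_family(rng, 10, np.full(3, 4.0))
        km = RiemannianKMeans(n_clusters=2, random_state=0).fit(np.concatenate([a, b]))
        pred = km.predict(diagonal_family(rng, 5, np.zeros(3)))
        assert len(set(pred)) == 1


class TestNormality:
    def test_stouffer_fixed_point(self):
        assert combine_pvalues_stouffer([0.5, 0.5]) == pytest.approx(0.5, abs=1e-12)

    def test_stouffer_reinforces_evidence(self):
        assert combine_pvalues_stouffer([0.04, 0.04]) < 0.04
        assert combine_pvalues_stouffer([0.96, 0.96]) > 0.96

    def test_k2_calibrated_under_lognormal_null(self):
        # ln(distance) Gaussian: the K2 test should accept most of the time
        hits = 0
        for seed in range(20):
            r = np.random.default_rng(seed)
            z = r.standard_normal(500)
            if scipy.stats.normaltest(z).pvalue > 0.05:
                hits += 1
        assert hits >= 18

    def test_k2_rejects_bimodal(self):
        hits = 0
        for seed in range(20):
            r = np.random.default_rng(seed)
            z = np.concatenate(
                [r.normal(-1.2, 0.3, 250), r.normal(1.2, 0.3, 250)]
            )
            if scipy.stats.normaltest(z).pvalue < 0.05:
                hits += 1
        assert hits == 20

    def test_undersized_cluster_scores_zero(self, rng):
        # two lumps of 15 and 10 epochs: k=1 is bimodal (non-normal) and
        # k=2 produces clusters below the K2 minimum, so both configurations
        # are invalid and the model falls back to the smallest k
        a = diagonal_family(rng, 15, np.zeros(3), jitter=0.2)
        b = diagonal_family(rng, 10, np.full(3, 5.0), jitter=0.2)
        covs = np.concatenate([a, b])
        assert covs.shape[0] < 2 * MIN_CLUSTER_SIZE
        model = RiemannianPotatoes(k_max=2, prereject=False, random_state=0).fit(covs)
        assert model.p_by_k_[1] == 0.0
        assert model.k_ == 1


class TestModelSelection:
    def test_well_separated_lognormal_clusters_recover_count(self, rng):
        # unequal sizes keep a merged configuration visibly bimodal
        fams = [
            tangent_cluster(rng, size, np.full(3, s))
            for size, s in ((80, 0.0), (60, 4.0), (45, 8.0))
        ]
        covs = np.concatenate(fams)
        model = select_cluster_count(covs, k_max=5, seed=3)
        assert model.k_ == 3
        assert model.combined_p_ > 0.05

    def test_k_max_honored(self, rng):
        fams = [tangent_cluster(rng, 40, np.full(3, s)) for s in (0.0, 4.0, 8.0)]
        model = select_cluster_count(np.concatenate(fams), k_max=2, seed=3)
        assert model.k_ <= 2

    def test_stats_counts_match_labels(self, rng):
        covs = random_spd_stack(rng, 80, 3)
        model = RiemannianPotatoes(k_max=3, prereject=False, random_state=1).fit(covs)
        for j, st in enumerate(model.stats_):
            assert st.count == int(np.sum(model.labels_ == j))

    def test_too_few_epochs_rejected(self, rng):
        with pytest.raises(ValueError):
            RiemannianPotatoes(prereject=False).fit(random_spd_stack(rng, 10, 3))


class TestModelPersistence:
    def test_json_round_trip_preserves_scoring(self, tmp_path, rng):
        covs = random_spd_stack(rng, 60, 3)
        model = RiemannianPotatoes(k_max=2, prereject=False, random_state=0).fit(covs)
        path = tmp_path / "model.json"
        model.save(path)
        loaded = RiemannianPotatoes.load(path)
        assert loaded.k_ == model.k_
        np.testing.assert_allclose(loaded.centroids_, model.centroids_)
        test = random_spd_stack(rng, 10, 3)
        np.testing.assert_allclose(
            loaded.score_samples(test), model.score_samples(test), rtol=1e-12
        )
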