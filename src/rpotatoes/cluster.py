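"""Cluster construction on the SPD manifold.

The detector assumes clean sleep EEG does not form a single region on the
manifold of covariance matrices: spatial patterns differ across sleep
stages, so clean activity is modelled as several clusters ("potatoes").
Construction proceeds in three steps:

1. pre-rejection — epochs whose mean pairwise distance to all other epochs
   exceeds the mean of those means are discarded as gross outliers;
2. k-means with the affine-invariant distance, centroids updated as
   geometric means;
3. model selection — k grows from 1 until the standardized distances of
   every cluster to its centroid look Gaussian (D'Agostino K2 per cluster,
   Stouffer-combined p-value above alpha).

A fitted :class:`RiemannianPotatoes` holds the centroids and per-cluster
geometric distance statistics and can standardize and score new windows.
"""

from __future__ import annotations

import json

import numpy as np
import scipy.stats
from sklearn.base import BaseEstimator, ClusterMixin

from .geometry import (
    DistanceStats,
    distance_stats,
    distances_to_reference,
    geometric_mean,
    pairwise_distances,
    standardize_distance,
)

__all__ = [
    "prereject_outliers",
    "RiemannianKMeans",
    "riemannian_kmeans",
    "combine_pvalues_stouffer",
    "cluster_normality_p",
    "RiemannianPotatoes",
    "select_cluster_count",
]

# Distances numerically equal to zero (epoch == centroid) are floored here
# before taking logs in Eq. 5-7 style statistics.
ZERO_DISTANCE_FLOOR = 1e-12

# D'Agostino's K2 needs a few dozen samples to be reliable; clusterings
# that produce a smaller cluster are scored as invalid (p = 0).
MIN_CLUSTER_SIZE = 20


def prereject_outliers(covs, precomputed_distances: np.ndarray | None = None):
    """Remove gross outlier epochs before clustering.

    For each epoch i, d_i is the mean distance to all other epochs; the
    threshold is the arithmetic mean of the d_i, and epochs with
    d_i > threshold are rejected.  Returns (kept_idx, rejected_idx, d).
    """
    covs = np.asarray(covs, dtype=float)
    if covs.shape[0] < 2:
        raise ValueError("need at least two covariance matrices")
    D = pairwise_distances(covs) if precomputed_distances is None else precomputed_distances
    N = D.shape[0]
    d = D.sum(axis=1) / (N - 1)
    threshold = d.mean()
    rejected = np.flatnonzero(d > threshold)
    kept = np.flatnonzero(~(d > threshold))
    return kept, rejected, d


class RiemannianKMeans(ClusterMixin, BaseEstimator):
    """k-means on the SPD manifold.

    Assignment uses the affine-invariant distance (ties broken toward the
    lowest cluster index); the update step replaces each centroid by the
    geometric mean of its members.  ``n_init`` restarts are run and the
    one with the lowest inertia kept: the first restart uses deterministic
    farthest-point (maximin) seeding, the remaining ones distance-weighted
    sampling (the k-means++ rule with squared manifold distances), all
    driven by ``random_state`` so a fit is reproducible.  An emptied
    cluster is reseeded with the point farthest from its own centroid.

    Parameters
    ----------
    n_clusters : number of clusters k.
    max_iter : cap on assignment/update rounds.
    random_state : seed for the initialization RNG.
    n_init : number of restarts (best inertia wins).
    tol, mean_max_iter : forwarded to the geometric-mean iteration.

    Attributes
    ----------
    cluster_centers_ : (k, n, n) centroid stack.
    labels_ : training assignment.
    inertia_ : sum of squared distances to assigned centroids.
    inertia_history_ : inertia after each assignment step.
    """

    def __init__(
        self,
        n_clusters: int = 2,
        max_iter: int = 100,
        random_state: int | None = None,
        n_init: int = 4,
        tol: float = 1e-7,
        mean_max_iter: int = 100,
    ):
        self.n_clusters = n_clusters
        self.max_iter = max_iter
        self.random_state = random_state
        self.n_init = n_init
        self.tol = tol
        self.mean_max_iter = mean_max_iter

    def _init_centroids(
        self, X: np.ndarray, rng: np.random.Generator, maximin: bool
    ) -> list[int]:
        N = X.shape[0]
        idx = [int(rng.integers(N))]
        closest_sq = distances_to_reference(X, X[idx[0]]) ** 2
        for _ in range(1, self.n_clusters):
            total = closest_sq.sum()
            if total <= 0:  # all points coincide with chosen seeds
                remaining = np.setdiff1d(np.arange(N), idx)
                idx.append(int(remaining[0]) if remaining.size else idx[-1])
                continue
            if maximin:
                nxt = int(np.argmax(closest_sq))
            else:
                nxt = int(rng.choice(N, p=closest_sq / total))
            idx.append(nxt)
            closest_sq = np.minimum(closest_sq, distances_to_reference(X, X[nxt]) ** 2)
        return idx

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        N = X.shape[0]
        k = self.n_clusters
        if k > N:
            raise ValueError(f"n_clusters={k} exceeds the {N} input matrices")
        rng = np.random.default_rng(self.random_state)
        best = None
        n_init = 1 if k == 1 else max(int(self.n_init), 1)
        for trial in range(n_init):
            out = self._fit_single(X, rng, maximin=trial == 0)
            if best is None or out[2][-1] < best[2][-1]:
                best = out
        centroids, labels, history = best
        self.cluster_centers_ = centroids
        self.labels_ = labels
        self.inertia_ = history[-1]
        self.inertia_history_ = history
        self.n_iter_ = len(history)
        return self

    def _fit_single(self, X: np.ndarray, rng: np.random.Generator, maximin: bool):
        N = X.shape[0]
        k = self.n_clusters
        centroids = X[self._init_centroids(X, rng, maximin)].copy()
        labels = np.full(N, -1, dtype=int)
        history: list[float] = []
        for _ in range(self.max_iter):
            dists = np.stack([distances_to_reference(X, c) for c in centroids], axis=1)
            new_labels = np.argmin(dists, axis=1)  # argmin takes the lowest index on ties
            # reseed any emptied cluster with the globally farthest point
            for j in range(k):
                if not np.any(new_labels == j):
                    far = int(np.argmax(dists[np.arange(N), new_labels]))
                    new_labels[far] = j
                    dists[far, :] = np.inf
                    dists[far, j] = 0.0
            history.append(float(np.sum(dists[np.arange(N), new_labels] ** 2)))
            if np.array_equal(new_labels, labels):
                break
            labels = new_labels
            for j in range(k):
                centroids[j] = geometric_mean(
                    X[labels == j], tol=self.tol, max_iter=self.mean_max_iter
                ).mean
        return centroids, labels, history

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        dists = np.stack(
            [distances_to_reference(X, c) for c in self.cluster_centers_], axis=1
        )
        return np.argmin(dists, axis=1)


def riemannian_kmeans(covs, k: int, seed: int | None = None, max_iter: int = 100):
    """Functional wrapper: returns (labels, centroids, inertia)."""
    km = RiemannianKMeans(n_clusters=k, max_iter=max_iter, random_state=seed).fit(covs)
    return km.labels_, km.cluster_centers_, km.inertia_


def combine_pvalues_stouffer(pvalues) -> float:
    """One-sided Stouffer combination: Z = sum Phi^-1(1 - p_j) / sqrt(k)."""
    p = np.clip(np.asarray(pvalues, dtype=float), 1e-300, 1 - 1e-16)
    z = scipy.stats.norm.ppf(1.0 - p)
    Z = z.sum() / np.sqrt(p.size)
    return float(1.0 - scipy.stats.norm.cdf(Z))


def _standardized_member_distances(distances: np.ndarray) -> tuple[np.ndarray, DistanceStats]:
    d = np.maximum(np.asarray(distances, dtype=float), ZERO_DISTANCE_FLOOR)
    stats = distance_stats(d)
    return standardize_distance(d, stats), stats


def cluster_normality_p(model: "RiemannianPotatoes") -> float:
    """Combined normality p-value of a fitted model's clusters.

    Each cluster's member distances to its centroid are standardized with
    that cluster's geometric statistics and tested with D'Agostino's K2
    omnibus test; the per-cluster p-values are Stouffer-combined.  A
    cluster smaller than MIN_CLUSTER_SIZE invalidates the configuration
    (returns 0.0).
    """
    pvals = []
    for j in range(model.k_):
        member_d = model.member_distances_[j]
        if member_d.size < MIN_CLUSTER_SIZE:
            return 0.0
        z, _ = _standardized_member_distances(member_d)
        pvals.append(scipy.stats.normaltest(z).pvalue)
    return combine_pvalues_stouffer(pvals)


class RiemannianPotatoes(BaseEstimator):
    """Clusters of clean activity on the SPD manifold, with model selection.

    ``fit`` takes a stack of training covariance matrices (N, n, n),
    optionally pre-rejects gross outliers, then runs manifold k-means for
    k = 1, 2, ..., ``k_max`` and keeps the first model whose combined
    cluster-normality p-value exceeds ``alpha`` (falling back to the
    largest p, ties toward smaller k).  The fitted model standardizes the
    distance of a new covariance matrix to its nearest centroid and maps
    it through the standard normal CDF into an outlier score.

    Attributes (after fit)
    ----------------------
    k_ : selected cluster count.
    centroids_ : (k, n, n) geometric-mean centroids O_j.
    stats_ : per-cluster DistanceStats (mu_j, sigma_j).
    labels_ : cluster index per retained training epoch.
    member_distances_ : list of per-cluster member distance arrays.
    combined_p_ : combined normality p-value of the selected model.
    p_by_k_ : combined p for each k tried.
    rejected_epochs_ : indices removed by pre-rejection.
    kept_epochs_ : indices retained.
    """

    def __init__(
        self,
        k_max: int = 10,
        alpha: float = 0.05,
        prereject: bool = True,
        random_state: int | None = None,
        kmeans_max_iter: int = 100,
        tol: float = 1e-7,
    ):
        self.k_max = k_max
        self.alpha = alpha
        self.prereject = prereject
        self.random_state = random_state
        self.kmeans_max_iter = kmeans_max_iter
        self.tol = tol

    def _evaluate_k(self, covs: np.ndarray, k: int) -> dict:
        km = RiemannianKMeans(
            n_clusters=k,
            max_iter=self.kmeans_max_iter,
            random_state=self.random_state,
            tol=self.tol,
        ).fit(covs)
        member_d, stats, pvals = [], [], []
        valid = True
        for j in range(k):
            d = distances_to_reference(covs[km.labels_ == j], km.cluster_centers_[j])
            member_d.append(d)
            if d.size < MIN_CLUSTER_SIZE:
                valid = False
                stats.append(None)
                continue
            z, st = _standardized_member_distances(d)
            stats.append(st)
            pvals.append(scipy.stats.normaltest(z).pvalue)
        p = combine_pvalues_stouffer(pvals) if valid else 0.0
        return {"km": km, "member_d": member_d, "stats": stats, "p": p}

    def fit(self, X, y=None):
        covs = np.asarray(X, dtype=float)
        if covs.ndim != 3 or covs.shape[1] != covs.shape[2]:
            raise ValueError("X must be a (N, n, n) stack of SPD matrices")
        if self.prereject:
            kept, rejected, d = prereject_outliers(covs)
        else:
            kept = np.arange(covs.shape[0])
            rejected = np.array([], dtype=int)
        retained = covs[kept]
        if retained.shape[0] < MIN_CLUSTER_SIZE:
            raise ValueError(
                f"only {retained.shape[0]} epochs retained; need at least "
                f"{MIN_CLUSTER_SIZE} to build a cluster model"
            )

        best = None
        best_k = 0
        p_by_k: list[float] = []
        for k in range(1, self.k_max + 1):
            if k > retained.shape[0]:
                break
            cand = self._evaluate_k(retained, k)
            p_by_k.append(cand["p"])
            # strict > keeps the smaller k on ties
            if best is None or cand["p"] > best["p"]:
                best, best_k = cand, k
            if cand["p"] > self.alpha:
                best, best_k = cand, k
                break

        km = best["km"]
        self.k_ = best_k
        self.centroids_ = km.cluster_centers_
        self.stats_ = best["stats"]
        self.labels_ = km.labels_
        self.member_distances_ = best["member_d"]
        self.combined_p_ = best["p"]
        self.p_by_k_ = p_by_k
        self.kept_epochs_ = kept
        self.rejected_epochs_ = rejected
        self.n_channels_ = covs.shape[1]
        return self

    # -- scoring -----------------------------------------------------------

    def _nearest(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        dists = np.stack(
            [distances_to_reference(X, c) for c in self.centroids_], axis=1
        )
        nearest = np.argmin(dists, axis=1)
        return nearest, dists[np.arange(X.shape[0]), nearest]

    def transform(self, X) -> np.ndarray:
        """Standardized distance of each matrix to its nearest centroid."""
        X = np.asarray(X, dtype=float)
        if X.ndim == 2:
            X = X[None]
        nearest, delta = self._nearest(X)
        delta = np.maximum(delta, ZERO_DISTANCE_FLOOR)
        out = np.empty(X.shape[0])
        for j in np.unique(nearest):
            st = self.stats_[j]
            out[nearest == j] = standardize_distance(delta[nearest == j], st)
        return out

    def score_samples(self, X) -> np.ndarray:
        """Outlier score Phi(standardized distance), rising with distance."""
        return scipy.stats.norm.cdf(self.transform(X))

    def predict(self, X, threshold: float = 0.95) -> np.ndarray:
        """Binary outlier flag at the given score threshold."""
        return (self.score_samples(X) >= threshold).astype(int)

    # -- persistence -------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "k": int(self.k_),
            "n_channels": int(self.n_channels_),
            "centroids": [c.tolist() for c in self.centroids_],
            "mu": [st.mu for st in self.stats_],
            "sigma": [st.sigma for st in self.stats_],
            "counts": [st.count for st in self.stats_],
            "combined_p": float(self.combined_p_),
            "config": self.get_params(),
        }

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_dict(cls, payload: dict) -> "RiemannianPotatoes":
        model = cls(**payload.get("config", {}))
        model.k_ = payload["k"]
        model.n_channels_ = payload["n_channels"]
        model.centroids_ = np.asarray(payload["centroids"], dtype=float)
        model.stats_ = [
            DistanceStats(mu=m, sigma=s, count=c)
            for m, s, c in zip(payload["mu"], payload["sigma"], payload["counts"])
        ]
        model.combined_p_ = payload.get("combined_p", float("nan"))
        return model

    @classmethod
    def load(cls, path) -> "RiemannianPotatoes":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def select_cluster_count(
    covs,
    k_max: int = 10,
    alpha: float = 0.05,
    seed: int | None = None,
    prereject: bool = False,
) -> RiemannianPotatoes:
    """Fit the cluster model with normality-based selection of k.

    ``covs`` are assumed already pre-rejected (pass ``prereject=True`` to
    run the outlier pre-rejection here instead).
    """
    return RiemannianPotatoes(
        k_max=k_max, alpha=alpha, prereject=prereject, random_state=seed
    ).fit(covs)
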