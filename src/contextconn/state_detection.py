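"""NC-state resolution: L1 k-means over window-wise graphs, model selection,
cluster-validity permutation testing, and split-half replication.

A network connectivity state (NC-state) is a recurring within-network edge
pattern: the centroid of a cluster of window-wise edge vectors. Clustering
uses k-means with L1 (cityblock) distance; the exact L1 minimizer of a
cluster is the coordinate-wise median, so centroid updates are medians
(k-medians). The state count k is chosen with an elbow rule on the
within-cluster sum of L1 distances (WCSS); validity is checked against
column-permutation nulls and replication against phase-randomized
split-half surrogates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.utils.validation import check_is_fitted, validate_data

from . import nulls
from ._utils import spawn_rng


class KMediansL1(ClusterMixin, BaseEstimator):
    """K-means clustering under the L1 (cityblock) metric.

    Lloyd-style alternation: windows are assigned to the nearest centroid in
    L1 distance, and each centroid is updated to the coordinate-wise median
    of its members (the exact L1 minimizer). The best of ``n_init`` random
    restarts by within-cluster sum of L1 distances is kept. An empty cluster
    is re-seeded from the point farthest from its current centroid.

    Parameters
    ----------
    n_clusters : int
        Number of states k.
    n_init : int
        Random restarts; the solution with the lowest inertia wins.
    max_iter : int
        Lloyd iterations per restart.
    random_state : int
        Seed; fitting is deterministic given the seed.

    Attributes
    ----------
    cluster_centers_ : (k, E) ndarray
    labels_ : (W,) ndarray
    inertia_ : float
        Sum over windows of L1 distance to the assigned centroid.
    n_iter_ : int
    """

    def __init__(self, n_clusters=2, n_init=10, max_iter=300, tol=0.0, random_state=0):
        self.n_clusters = n_clusters
        self.n_init = n_init
        self.max_iter = max_iter
        self.tol = tol
        self.random_state = random_state

    def _single_run(self, X, rng):
        W = X.shape[0]
        k = self.n_clusters
        centers = X[rng.choice(W, size=k, replace=False)].copy()
        labels = None
        history = []
        for it in range(self.max_iter):
            d = cdist(X, centers, metric="cityblock")
            new_labels = d.argmin(axis=1)
            for c in range(k):
                members = X[new_labels == c]
                if members.shape[0] == 0:
                    far = d.min(axis=1).argmax()
                    centers[c] = X[far]
                    new_labels[far] = c
                else:
                    centers[c] = np.median(members, axis=0)
            inertia = float(
                np.abs(X - centers[new_labels]).sum()
            )
            history.append(inertia)
            if labels is not None and np.array_equal(labels, new_labels):
                labels = new_labels
                break
            labels = new_labels
        return centers, labels, history[-1], len(history), history

    def fit(self, X, y=None):
        X = validate_data(self, X, dtype=float)
        W = X.shape[0]
        if not (W > self.n_clusters >= 1):
            if W == self.n_clusters:
                # degenerate: every window its own state
                self.cluster_centers_ = X.copy()
                self.labels_ = np.arange(W)
                self.inertia_ = 0.0
                self.n_iter_ = 0
                self.wcss_history_ = [0.0]
                return self
            raise ValueError(f"need W > k >= 1, got W={W}, k={self.n_clusters}")
        best = None
        for init in range(self.n_init):
            rng = spawn_rng(self.random_state, init)
            run = self._single_run(X, rng)
            if best is None or run[2] < best[2]:
                best = run
        self.cluster_centers_, self.labels_, self.inertia_, self.n_iter_, self.wcss_history_ = best
        return self

    def predict(self, X):
        check_is_fitted(self)
        X = validate_data(self, X, reset=False, dtype=float)
        return cdist(X, self.cluster_centers_, metric="cityblock").argmin(axis=1)

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_


@dataclass
class NCStateModel:
    """Fitted NC-states for one (pseudo-)network."""

    network: object
    k: int
    centroids: np.ndarray
    assignments: np.ndarray  # one state index per non-censored window (concatenated subjects)
    wcss: float
    distance: str = "L1"

    def state_windows(self, state: int) -> np.ndarray:
        return np.nonzero(self.assignments == state)[0]


@dataclass
class ReplicationReport:
    """Split-half replication of each NC-state centroid."""

    similarity: np.ndarray          # per state, r between matched half centroids
    chance_quantile: np.ndarray     # per state, (1-alpha) quantile of surrogate r
    chance_mean: np.ndarray
    replicated: np.ndarray          # both criteria hold
    r_threshold: float
    alpha: float


def fit_ncstates(windows, k: int, restarts: int = 50, seed: int = 0, network=None) -> NCStateModel:
    """Fit k NC-states to a W x E window matrix (best of ``restarts`` by WCSS)."""
    est = KMediansL1(n_clusters=k, n_init=restarts, random_state=seed).fit(windows)
    return NCStateModel(
        network=network,
        k=k,
        centroids=est.cluster_centers_,
        assignments=est.labels_,
        wcss=est.inertia_,
    )


def select_k_elbow(windows, k_range, restarts: int = 20, seed: int = 0, threshold: float = 0.05):
    """Smallest k whose fractional WCSS improvement to k+1 drops below threshold.

    Returns (k_star, [(k, wcss), ...]). The WCSS curve is smoothed by a
    cumulative minimum if restart noise makes it non-monotone.
    """
    k_range = sorted(k_range)
    if len(k_range) < 3:
        raise ValueError("k_range must contain at least 3 values")
    wcss = []
    for k in k_range:
        wcss.append(fit_ncstates(windows, k, restarts=restarts, seed=seed).wcss)
    wcss = np.asarray(wcss)
    if np.any(np.diff(wcss) > 1e-9):
        warnings.warn("WCSS curve not monotone (restart noise); smoothing by cumulative min")
        wcss = np.minimum.accumulate(wcss)
    k_star = k_range[-1]
    for idx in range(len(k_range) - 1):
        improvement = (wcss[idx] - wcss[idx + 1]) / wcss[idx] if wcss[idx] > 0 else 0.0
        if improvement < threshold:
            k_star = k_range[idx]
            break
    return k_star, list(zip(k_range, wcss.tolist()))


def clustering_validity_test(windows, k: int, n_perm: int = 199, seed: int = 0, restarts: int = 5) -> float:
    """Permutation test that k-state structure beats column-shuffled nulls.

    Each null dataset permutes every edge column independently (preserving
    marginal distributions, destroying inter-edge relations); p is the
    +1-corrected fraction of null WCSS values at or below the observed WCSS.
    Small p supports real cluster structure.
    """
    if n_perm < 19:
        raise ValueError("n_perm must be >= 19")
    observed = fit_ncstates(windows, k, restarts=restarts, seed=seed).wcss
    null = np.empty(n_perm)
    for b in range(n_perm):
        perm = nulls.permute_observations(windows, seed=seed * 1000 + b)
        null[b] = fit_ncstates(perm, k, restarts=restarts, seed=seed).wcss
    return float((1 + np.sum(null <= observed)) / (n_perm + 1))


def _match_centroids(c1: np.ndarray, c2: np.ndarray) -> np.ndarray:
    """Greedy match each row of c1 to its most-correlated row of c2; returns r per c1 row."""
    k = c1.shape[0]
    r = np.corrcoef(np.vstack([c1, c2]))[:k, k:]
    sims = np.empty(k)
    for i in range(k):
        sims[i] = r[i].max()
    return sims


def split_half_replication(
    windows,
    subject_ids,
    k: int,
    n_surr: int = 100,
    seed: int = 0,
    restarts: int = 10,
    r_threshold: float = 0.8,
    alpha: float = 0.05,
) -> ReplicationReport:
    """Split subjects in half, refit states per half, test centroid similarity.

    Each half-1 centroid is matched greedily to the most-correlated half-2
    centroid. A state replicates iff (1) r > ``r_threshold`` and (2) r
    exceeds the (1 - alpha) quantile of similarities computed identically on
    phase-randomized edge timeseries.
    """
    windows = np.asarray(windows, dtype=float)
    subject_ids = np.asarray(subject_ids)
    subjects = list(dict.fromkeys(subject_ids.tolist()))
    if len(subjects) < 4:
        raise ValueError("need >= 2 subjects per half")
    rng = spawn_rng(seed, 77)
    order = rng.permutation(len(subjects))
    half1 = {subjects[i] for i in order[: len(subjects) // 2]}
    m1 = np.isin(subject_ids, list(half1))
    if min(m1.sum(), (~m1).sum()) <= k:
        raise ValueError("k exceeds windows available in a half")

    def half_similarity(mat):
        f1 = fit_ncstates(mat[m1], k, restarts=restarts, seed=seed)
        f2 = fit_ncstates(mat[~m1], k, restarts=restarts, seed=seed + 1)
        return _match_centroids(f1.centroids, f2.centroids)

    observed = half_similarity(windows)
    surr = np.empty((n_surr, k))
    for b in range(n_surr):
        # phase-randomize each subject's edge timeseries (windows x edges -> per-subject)
        shifted = windows.copy()
        for s in subjects:
            rows = np.nonzero(subject_ids == s)[0]
            shifted[rows] = nulls.phase_randomize(
                windows[rows].T, seed=seed * 10000 + b * 100 + int(rows[0])
            ).T
        surr[b] = np.sort(half_similarity(shifted))[::-1][:k]
    chance_q = np.quantile(surr, 1 - alpha, axis=0)
    replicated = (observed > r_threshold) & (observed > chance_q)
    return ReplicationReport(
        similarity=observed,
        chance_quantile=chance_q,
        chance_mean=surr.mean(axis=0),
        replicated=replicated,
        r_threshold=r_threshold,
        alpha=alpha,
    )
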