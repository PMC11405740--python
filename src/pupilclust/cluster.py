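"""Euclidean k-means over pupil trajectory vectors.

Lloyd's algorithm with k-means++ seeding and best-of-``n_init`` restart
selection by inertia.  The loop is written out (rather than delegated)
because the analysis contract asserts inertia monotonicity at every
iteration and prescribes the empty-cluster rule: a centroid that loses all
members is re-seeded at the point farthest from its assigned centroid.

For two clusters, labels are aligned to a reporting convention taken from
the trajectory phenotypes: cluster 0 is the cluster whose centroid has the
larger mean over the first level of the first block (the "high initial
pupil response" group).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from sklearn.cluster import kmeans_plusplus
from sklearn.metrics import adjusted_rand_score

from pupilclust.schedule import TaskSchedule, level_windows

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ClusteringResult:
    labels: np.ndarray            # participant index -> cluster index
    centroids: np.ndarray         # (k, n_trials)
    inertia: float
    k: int
    seed: int
    n_init: int
    aligned: bool = False

    def __post_init__(self) -> None:
        if self.inertia < 0 or not np.isfinite(self.centroids).all():
            raise ValueError("invalid clustering result")

    def to_manifest(self, path, participant_ids=None) -> None:
        payload = {"k": self.k, "seed": self.seed, "n_init": self.n_init,
                   "inertia": float(self.inertia), "aligned": self.aligned,
                   "cluster_sizes": np.bincount(self.labels, minlength=self.k).tolist()}
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def _lloyd(X: np.ndarray, centers: np.ndarray, max_iter: int, tol: float):
    inertia_prev = np.inf
    labels = None
    for _ in range(max_iter):
        d2 = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        labels = d2.argmin(axis=1)
        inertia = d2[np.arange(len(X)), labels].sum()
        # empty-cluster rule: re-seed at the point farthest from its centroid
        for j in range(len(centers)):
            if not (labels == j).any():
                far = d2[np.arange(len(X)), labels].argmax()
                centers[j] = X[far]
                labels[far] = j
                inertia = (((X - centers[labels]) ** 2).sum(axis=1)).sum()
        assert inertia <= inertia_prev + 1e-8, "Lloyd inertia increased"
        new_centers = np.vstack([X[labels == j].mean(axis=0) for j in range(len(centers))])
        shift = np.linalg.norm(new_centers - centers)
        centers = new_centers
        if shift < tol:
            inertia_prev = inertia
            break
        inertia_prev = inertia
    d2 = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
    labels = d2.argmin(axis=1)
    inertia = float(d2[np.arange(len(X)), labels].sum())
    return labels, centers, inertia


def kmeans_fit(vectors: np.ndarray, k: int = 2, n_init: int = 25,
               max_iter: int = 300, tol: float = 1e-6,
               seed: int = 0) -> ClusteringResult:
    """Best-of-restarts Euclidean k-means on a participants x trials matrix."""
    X = np.asarray(vectors, dtype=float)
    if X.ndim != 2:
        raise ValueError("vectors must be a 2-D matrix")
    if not np.isfinite(X).all():
        raise ValueError("vectors must be finite")
    if len(X) < k:
        raise ValueError(f"need at least k={k} vectors, got {len(X)}")
    rng = np.random.default_rng(seed)
    best = None
    for _ in range(n_init):
        init, _ = kmeans_plusplus(X, n_clusters=k,
                                  random_state=int(rng.integers(2**31 - 1)))
        labels, centers, inertia = _lloyd(X, init.copy(), max_iter, tol)
        if best is None or inertia < best[2]:
            best = (labels, centers, inertia)
    labels, centers, inertia = best
    return ClusteringResult(labels=labels, centroids=centers, inertia=inertia,
                            k=k, seed=seed, n_init=n_init)


def align_labels(result: ClusteringResult, vectors: np.ndarray,
                 schedule: TaskSchedule) -> ClusteringResult:
    """Fix the two-cluster label convention.

    Cluster 0 becomes the cluster whose centroid has the larger mean over
    the block-1 level-1 trial window (the group starting the task with the
    stronger pupil response).  Idempotent and invariant to the arbitrary
    label permutation k-means returns.
    """
    if result.k != 2:
        raise ValueError("label alignment is defined for k = 2")
    win = level_windows(schedule)[0]
    start_means = result.centroids[:, win.first_trial:win.last_trial].mean(axis=1)
    if start_means[0] == start_means[1]:
        # exact tie: order by within-cluster inertia contribution
        logger.warning("centroid start-window means tied; ordering by inertia contribution")
        contrib = [
            ((vectors[result.labels == j] - result.centroids[j]) ** 2).sum()
            for j in (0, 1)
        ]
        keep = contrib[0] <= contrib[1]
    else:
        keep = start_means[0] > start_means[1]
    if keep:
        return replace(result, aligned=True)
    return replace(result,
                   labels=1 - result.labels,
                   centroids=result.centroids[::-1].copy(),
                   aligned=True)


def adjusted_rand(labels: np.ndarray, truth: np.ndarray) -> float:
    """Chance-corrected agreement between a clustering and ground truth."""
    labels = np.asarray(labels)
    truth = np.asarray(truth)
    if len(labels) != len(truth):
        raise ValueError("label vectors must have equal length")
    return float(adjusted_rand_score(truth, labels))


def silhouette_by_k(vectors: np.ndarray, k_values=(2, 3, 4, 5), seed: int = 0,
                    n_init: int = 10) -> dict[int, float]:
    """Mean silhouette score for a range of k, for reporting only.

    The pipeline never auto-selects k from this; k = 2 is the analysis
    default and model selection is left to the reader of the report.
    """
    from sklearn.metrics import silhouette_score

    out = {}
    for k in k_values:
        res = kmeans_fit(vectors, k=k, n_init=n_init, seed=seed)
        out[k] = float(silhouette_score(vectors, res.labels))
    return out
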