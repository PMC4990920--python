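"""Microstate discretization in the projected (tICA) space.

k-centers is the default: a deterministic farthest-point traversal whose
cover radius is within a factor of two of the optimal k-center radius.
Lloyd-iteration k-means is provided for parity, initialized from the
k-centers solution so both methods are bit-reproducible.  The metric is
plain Euclidean distance in the projected space.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.base import BaseEstimator, ClusterMixin

__all__ = ["KCenters", "KMeansLloyd", "k_centers", "k_means", "assign"]


def _pool(data) -> np.ndarray:
    if isinstance(data, np.ndarray):
        return np.atleast_2d(data.astype(float))
    return np.vstack([np.atleast_2d(np.asarray(d, dtype=float)) for d in data])


def _assign(centers: np.ndarray, X: np.ndarray) -> np.ndarray:
    # nearest center by Euclidean distance; ties go to the lowest center index
    dist = cdist(X, centers)
    return np.argmin(dist, axis=1)


class KCenters(BaseEstimator, ClusterMixin):
    """Deterministic farthest-point (k-centers) clustering.

    The first center is the frame at ``start_index`` (default 0); each next
    center is the frame farthest from its nearest existing center, ties
    broken by lowest frame index.  Deterministic by construction, so pipeline
    outputs are bit-reproducible.
    """

    def __init__(self, k: int, start_index: int = 0):
        self.k = k
        self.start_index = start_index

    def fit(self, X, y=None):
        X = _pool(X)
        k = int(self.k)
        if k < 1:
            raise ValueError("k must be >= 1")
        if k > X.shape[0]:
            raise ValueError(f"k ({k}) exceeds the number of frames ({X.shape[0]})")
        center_idx = [int(self.start_index)]
        d_nearest = np.linalg.norm(X - X[center_idx[0]], axis=1)
        while len(center_idx) < k:
            # argmax returns the lowest index among ties
            nxt = int(np.argmax(d_nearest))
            center_idx.append(nxt)
            d_new = np.linalg.norm(X - X[nxt], axis=1)
            d_nearest = np.minimum(d_nearest, d_new)
        self.center_indices_ = np.array(center_idx)
        self.cluster_centers_ = X[self.center_indices_].copy()
        self.labels_ = _assign(self.cluster_centers_, X)
        self.cover_radius_ = float(d_nearest.max())
        return self

    def predict(self, X):
        return _assign(self.cluster_centers_, _pool(X))


class KMeansLloyd(BaseEstimator, ClusterMixin):
    """Lloyd k-means initialized from the k-centers solution.

    Converges when the largest center movement drops below ``tol`` (1e-8) or
    after ``max_iter`` (500) sweeps.  An emptied cluster is re-seeded at the
    point farthest from its nearest center.
    """

    def __init__(self, k: int, start_index: int = 0, tol: float = 1e-8,
                 max_iter: int = 500):
        self.k = k
        self.start_index = start_index
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, X, y=None):
        X = _pool(X)
        centers = KCenters(k=self.k, start_index=self.start_index).fit(X).cluster_centers_
        for iteration in range(self.max_iter):
            labels = _assign(centers, X)
            new_centers = centers.copy()
            for j in range(int(self.k)):
                members = X[labels == j]
                if members.shape[0] == 0:
                    # documented policy: re-seed at the farthest point
                    d = cdist(X, new_centers).min(axis=1)
                    new_centers[j] = X[int(np.argmax(d))]
                else:
                    new_centers[j] = members.mean(axis=0)
            shift = np.linalg.norm(new_centers - centers, axis=1).max()
            centers = new_centers
            if shift < self.tol:
                break
        self.cluster_centers_ = centers
        self.labels_ = _assign(centers, X)
        self.n_iter_ = iteration + 1
        self.inertia_ = float(
            ((X - centers[self.labels_]) ** 2).sum()
        )
        return self

    def predict(self, X):
        return _assign(self.cluster_centers_, _pool(X))


def k_centers(data, k: int, start_index: int = 0) -> KCenters:
    return KCenters(k=k, start_index=start_index).fit(_pool(data))


def k_means(data, k: int, start_index: int = 0) -> KMeansLloyd:
    return KMeansLloyd(k=k, start_index=start_index).fit(_pool(data))


def assign(model, data) -> np.ndarray:
    """Nearest-center state labels for each frame (ties to lowest index)."""
    X = _pool(data)
    if X.shape[1] != model.cluster_centers_.shape[1]:
        raise ValueError(
            f"data dimension {X.shape[1]} does not match model dimension "
            f"{model.cluster_centers_.shape[1]}"
        )
    return _assign(model.cluster_centers_, X)
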