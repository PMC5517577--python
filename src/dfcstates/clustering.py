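"""k-means clustering of connectivity vectors under correlation distance.

Windows are grouped into dynamic connectivity states: vectors with a
similar correlation *pattern* fall in the same cluster regardless of the
magnitude of their entries.  Correlation distance ``1 - r(u, v)`` is
implemented exactly by standardizing every vector to zero mean and unit
norm and running Lloyd iterations in Euclidean space, with centroids
re-standardized after every update; the best of many replicates (by
total within-cluster correlation distance) is kept.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.cluster import kmeans_plusplus


class ConstantVectorError(ValueError):
    """Correlation distance is undefined for a constant vector."""


def _standardize(x: np.ndarray) -> np.ndarray:
    """Map rows to zero mean, unit norm (so 1 - u.v is correlation distance)."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    centered = x - x.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1, keepdims=True)
    if (norms == 0).any():
        raise ConstantVectorError("constant vector has undefined correlation")
    return centered / norms


def correlation_distance(u: np.ndarray, v: np.ndarray) -> float:
    """``1 - Pearson(u, v)``; 0 for identical patterns, 2 for sign-flipped."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise ValueError("vectors must have equal length")
    su, sv = _standardize(u)[0], _standardize(v)[0]
    return float(1.0 - su @ sv)


@dataclass(frozen=True)
class ClusterModel:
    """Result of correlation-distance k-means.

    ``centroids`` are stored in standardized form (zero mean, unit norm);
    ``inertia`` is the total within-cluster correlation distance of the
    winning replicate.
    """

    k: int
    centroids: np.ndarray
    assignments: np.ndarray
    inertia: float
    replicates: int
    seed: int
    n_iter: int

    def predict(self, vectors: np.ndarray) -> np.ndarray:
        """Assign new vectors to the nearest centroid (correlation distance)."""
        x = _standardize(vectors)
        return np.argmax(x @ self.centroids.T, axis=1)


def _lloyd(
    x: np.ndarray, k: int, rng: np.random.Generator, max_iter: int
) -> tuple[np.ndarray, np.ndarray, float, int]:
    """One replicate: k-means++ init, Lloyd iterations on standardized data."""
    n = len(x)
    seed_int = int(rng.integers(2**31 - 1))
    centers, _ = kmeans_plusplus(x, n_clusters=k, random_state=seed_int)
    c = _standardize(centers)
    assign = np.full(n, -1)
    it = 0
    for it in range(1, max_iter + 1):
        sims = x @ c.T
        new_assign = np.argmax(sims, axis=1)
        # empty-cluster repair: re-seed from the point farthest from its centroid
        for cluster in range(k):
            if not (new_assign == cluster).any():
                worst = int(np.argmin(sims[np.arange(n), new_assign]))
                new_assign[worst] = cluster
                sims[worst] = 0.0
        if (new_assign == assign).all():
            break
        assign = new_assign
        for cluster in range(k):
            members = x[assign == cluster]
            c[cluster] = members.mean(axis=0)
        c = _standardize(c)
    final_sims = x @ c.T
    inertia = float(np.sum(1.0 - final_sims[np.arange(n), assign]))
    return c, assign, inertia, it


def cluster_states(
    vectors: np.ndarray,
    k: int,
    replicates: int = 100,
    seed: int = 0,
    max_iter: int = 300,
) -> ClusterModel:
    """Cluster pooled connectivity vectors into ``k`` states.

    Runs ``replicates`` independent k-means++ initializations and keeps
    the replicate with the lowest total within-cluster correlation
    distance.  Deterministic given ``seed``.
    """
    x = _standardize(vectors)
    n = len(x)
    if n < k:
        raise ValueError(f"need at least k={k} vectors, got {n}")
    rng = np.random.default_rng(seed)
    best: tuple | None = None
    for _ in range(replicates):
        c, assign, inertia, it = _lloyd(x, k, rng, max_iter)
        if best is None or inertia < best[2] - 1e-12:
            best = (c, assign, inertia, it)
    c, assign, inertia, it = best
    return ClusterModel(
        k=k,
        centroids=c,
        assignments=assign,
        inertia=inertia,
        replicates=replicates,
        seed=seed,
        n_iter=it,
    )


def state_mean_matrix(
    model: ClusterModel, cluster: int, matrices: np.ndarray | list[np.ndarray]
) -> np.ndarray:
    """Element-wise mean of the member correlation matrices of one state.

    Correlations are averaged directly (no Fisher transform), matching
    how a state's representative matrix is defined.
    """
    matrices = np.asarray(matrices)
    members = matrices[model.assignments == cluster]
    if len(members) == 0:
        raise ValueError(f"cluster {cluster} is empty")
    return members.mean(axis=0)
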