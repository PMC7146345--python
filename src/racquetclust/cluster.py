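"""Lloyd K-means with the exact semantics the hybrid model layers rely on.

The layers need guarantees a generic library fit does not make explicit:
centers that equal the mean of their assigned points at convergence, an
SSE that is verified non-increasing across every Lloyd iteration, and
empty clusters re-seeded to the point farthest from its assigned center.
Seeding is k-means++.  The objective is the sum of squared errors

    SSE = sum_i sum_{x in C_i} ||x - mu_i||².
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist


@dataclass
class KMeansResult:
    """Converged clustering: centers are the means of their assigned points."""

    centers: np.ndarray  # (k, d)
    assignments: np.ndarray  # (n,) cluster index per point
    sse: float
    k: int
    n_iter: int


def _kmeanspp_init(X: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    n = X.shape[0]
    centers = np.empty((k, X.shape[1]))
    centers[0] = X[rng.integers(n)]
    d2 = np.sum((X - centers[0]) ** 2, axis=1)
    for i in range(1, k):
        total = d2.sum()
        if total <= 0:
            # all remaining mass at distance 0: pick any distinct point
            centers[i] = X[rng.integers(n)]
        else:
            centers[i] = X[rng.choice(n, p=d2 / total)]
        d2 = np.minimum(d2, np.sum((X - centers[i]) ** 2, axis=1))
    return centers


def kmeans(points, k: int, seed: int = 0, max_iter: int = 300, tol: float = 1e-9,
           n_init: int = 10) -> KMeansResult:
    """Cluster ``points`` into ``k`` groups by Lloyd iterations.

    ``points`` may be (n,) scalars or an (n, d) array.  Requires
    k <= number of distinct points.  Runs ``n_init`` restarts from
    k-means++ seedings (seeds derived deterministically from ``seed``)
    and keeps the lowest-SSE result; each restart iterates until the
    largest center shift falls below ``tol`` or ``max_iter`` is reached,
    re-seeding an empty cluster to the point currently farthest from its
    center.
    """
    best = None
    for i in range(max(1, n_init)):
        res = _kmeans_single(points, k, seed + 17 * i, max_iter, tol)
        if best is None or res.sse < best.sse:
            best = res
    return best


def _kmeans_single(points, k: int, seed: int, max_iter: int, tol: float) -> KMeansResult:
    X = np.asarray(points, dtype=float)
    squeeze = X.ndim == 1
    if squeeze:
        X = X[:, None]
    if X.ndim != 2 or X.shape[0] == 0:
        raise ValueError("points must be a non-empty 1-D or 2-D array")
    n_distinct = np.unique(X, axis=0).shape[0]
    if k < 1 or k > n_distinct:
        raise ValueError(f"k must satisfy 1 <= k <= {n_distinct} distinct points, got {k}")

    rng = np.random.default_rng(seed)
    centers = _kmeanspp_init(X, k, rng)
    prev_sse = np.inf
    assign = np.zeros(len(X), dtype=int)
    for it in range(1, max_iter + 1):
        D = cdist(X, centers, metric="sqeuclidean")
        assign = np.argmin(D, axis=1)
        point_d2 = D[np.arange(len(X)), assign]
        # re-seed empty clusters to the farthest point
        for c in range(k):
            if not np.any(assign == c):
                far = int(np.argmax(point_d2))
                centers[c] = X[far]
                assign[far] = c
                point_d2[far] = 0.0
        sse = float(point_d2.sum())
        assert sse <= prev_sse + 1e-9, f"SSE increased across Lloyd iteration: {prev_sse} -> {sse}"
        prev_sse = sse
        new_centers = np.array([X[assign == c].mean(axis=0) for c in range(k)])
        shift = float(np.max(np.linalg.norm(new_centers - centers, axis=1)))
        centers = new_centers
        if shift < tol:
            break
    # final assignment against the converged centers, then exact means
    D = cdist(X, centers, metric="sqeuclidean")
    assign = np.argmin(D, axis=1)
    for c in range(k):
        if np.any(assign == c):
            centers[c] = X[assign == c].mean(axis=0)
    sse = float(np.sum((X - centers[assign]) ** 2))
    return KMeansResult(
        centers=centers[:, 0] if squeeze else centers,
        assignments=assign,
        sse=sse,
        k=k,
        n_iter=it,
    )
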