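"""Independent brute-force oracles used by the unit and acceptance tests.

These deliberately avoid the library's own implementations: K-means is
checked against exhaustive enumeration of all assignments, DBSCAN against
a literal density-reachability construction, and the complementary filter
against a plain Python loop.
"""

from itertools import product

import numpy as np


def exhaustive_kmeans_sse(X: np.ndarray, k: int) -> float:
    """Optimal k-clustering SSE by enumerating every assignment vector.

    Uses the identity SSE = sum|x|^2 - sum_c |sum_c|^2 / n_c to score all
    k^n assignments in one vectorized pass.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n = len(X)
    assigns = np.array(list(product(range(k), repeat=n)))  # (P, n)
    onehot = np.eye(k)[assigns]  # (P, n, k)
    counts = onehot.sum(axis=1)  # (P, k)
    sums = np.einsum("pnk,nd->pkd", onehot, X)  # (P, k, d)
    sq = np.einsum("pkd,pkd->pk", sums, sums)
    with np.errstate(divide="ignore", invalid="ignore"):
        contrib = np.where(counts > 0, sq / np.where(counts > 0, counts, 1), 0.0)
    sse = (X ** 2).sum() - contrib.sum(axis=1)
    return float(sse.min())


def brute_force_dbscan(X: np.ndarray, eps: float, min_pts: int) -> np.ndarray:
    """Literal DBSCAN: core points, density reachability, noise = -1.

    Follows the textbook definition with min_pts counting the point
    itself; border points join the first core point's cluster that
    reaches them (scan order), which matches partition equality up to
    border-point ties — comparisons should treat clusters as sets of
    core points plus their reachable borders.
    """
    X = np.asarray(X, dtype=float)
    n = len(X)
    d = np.linalg.norm(X[:, None, :] - X[None, :, :], axis=2)
    neighbors = [np.flatnonzero(d[i] <= eps) for i in range(n)]
    core = np.array([len(nb) >= min_pts for nb in neighbors])
    labels = np.full(n, -1)
    cluster = 0
    for i in range(n):
        if not core[i] or labels[i] != -1:
            continue
        # expand the cluster from this core point
        labels[i] = cluster
        frontier = [i]
        while frontier:
            j = frontier.pop()
            for q in neighbors[j]:
                if labels[q] == -1:
                    labels[q] = cluster
                    if core[q]:
                        frontier.append(q)
        cluster += 1
    return labels


def hbl_loop_oracle(gyro, accel_angle_corr, alpha, T, theta0):
    """Plain-loop complementary recursion (the stated update rule)."""
    out = []
    prev = theta0
    for g, a in zip(gyro, accel_angle_corr):
        prev = alpha * (prev + g * T) + (1.0 - alpha) * a
        out.append(prev)
    return np.asarray(out)
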