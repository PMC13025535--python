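"""k-nearest-neighbor distances under the Euclidean metric.

This is the computational engine underneath every estimator in the
package: both the invariant measure (median 1-NN distance) and the
Kozachenko--Leonenko entropy estimator consume the distance from each
sample point to its k-th nearest neighbor, excluding the point itself.

One-dimensional inputs use an O(N log N) sort-based path (the k nearest
neighbors of a point on the line lie among its k predecessors and k
successors in sorted order); higher dimensions use a KD-tree.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

__all__ = ["DistanceVector", "as_point_matrix", "knn_distances"]


@dataclass(frozen=True)
class DistanceVector:
    """Per-point distance to the k-th nearest neighbor.

    Attributes
    ----------
    dists : ndarray, shape (n,)
        Non-negative distances; entry ``i`` excludes the self-distance.
    k : int
        Neighbor order used.
    metric : str
        Always ``"euclidean"``.
    """

    dists: np.ndarray
    k: int
    metric: str = field(default="euclidean")

    def __len__(self) -> int:
        return len(self.dists)


def as_point_matrix(points) -> np.ndarray:
    """Coerce input to a validated N x d float matrix.

    1-D input becomes an (N, 1) column. Raises ``ValueError`` on
    non-finite entries or fewer than two points.
    """
    x = np.asarray(points, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    if x.ndim != 2:
        raise ValueError(f"points must be 1-D or 2-D, got ndim={x.ndim}")
    if x.shape[0] < 2:
        raise ValueError("need at least 2 points")
    if not np.all(np.isfinite(x)):
        bad = np.unique(np.nonzero(~np.isfinite(x))[0])
        raise ValueError(f"non-finite entries at rows {bad.tolist()}")
    return x


def _knn_1d_sorted(x: np.ndarray, k: int) -> np.ndarray:
    """Sort-based k-th NN distances for a flat 1-D sample."""
    n = x.shape[0]
    order = np.argsort(x, kind="stable")
    xs = x[order]
    # candidate distances to the k predecessors and k successors
    cand = np.full((n, 2 * k), np.inf)
    for j in range(1, k + 1):
        gap = xs[j:] - xs[:-j]
        cand[j:, j - 1] = gap
        cand[: n - j, k + j - 1] = gap
    kth = np.partition(cand, k - 1, axis=1)[:, k - 1]
    out = np.empty(n)
    out[order] = kth
    return out


def knn_distances(points, k: int, *, jitter: bool = False,
                  jitter_seed: int = 0) -> DistanceVector:
    """Distance from each point to its k-th nearest neighbor.

    Parameters
    ----------
    points : array-like, shape (n,) or (n, d)
        Sample; rows are observations.
    k : int
        Neighbor order (k >= 1). Requires n >= k + 1.
    jitter : bool
        Exact duplicate points produce zero distances, which break the
        logarithm in the entropy estimator; by default they raise. With
        ``jitter=True`` a deterministic symmetry-breaking perturbation of
        magnitude 1e-10 x the per-column interquartile range is added
        before computing distances.
    jitter_seed : int
        Seed for the jitter stream (ignored unless ``jitter``).

    Returns
    -------
    DistanceVector

    Raises
    ------
    ValueError
        If n <= k ("not enough points"), entries are non-finite, or a
        zero distance is found (duplicate points) with ``jitter=False``.
    """
    x = as_point_matrix(points)
    k = int(k)
    if k < 1:
        raise ValueError("k must be >= 1")
    n, d = x.shape
    if n <= k:
        raise ValueError(f"not enough points: need N >= k+1 = {k + 1}, got N = {n}")

    if jitter:
        rng = np.random.default_rng(jitter_seed)
        q75, q25 = np.percentile(x, [75, 25], axis=0)
        scale = q75 - q25
        span = x.max(axis=0) - x.min(axis=0)
        scale = np.where(scale > 0, scale, np.where(span > 0, span, 1.0))
        x = x + rng.uniform(-1.0, 1.0, size=x.shape) * (1e-10 * scale)

    if d == 1:
        dists = _knn_1d_sorted(x[:, 0], k)
    else:
        tree = cKDTree(x)
        # k+1 because the query set is the data itself (self-match at 0)
        dd, _ = tree.query(x, k=k + 1)
        dists = dd[:, k]

    if np.any(dists == 0.0):
        idx = np.nonzero(dists == 0.0)[0]
        raise ValueError(
            "zero k-NN distance (duplicate points) at indices "
            f"{idx.tolist()[:10]}; pass jitter=True to break ties"
        )
    return DistanceVector(dists=dists, k=k)
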