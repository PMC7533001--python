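"""Hair-follicle counting from skeleton endpoints.

Each hair emerges from a follicular opening, and several hairs can share
one opening. The feature image (erosion branch, so specular holes are
closed) is thinned to a one-pixel skeleton; skeleton *endpoints* —
pixels with exactly one true 8-neighbor — mark hair tips and roots.
Endpoints, standardized to the unit square, are clustered with K-means,
and the follicle count is the number of non-empty clusters.

The number of clusters is not known in advance. The selection rule fits
one K-means solution per candidate k = 1..n (n = number of endpoints),
each from a fresh Gaussian initialization and a deliberately small
iteration budget, and keeps the solution with the smallest
sum-of-squared-distances loss. Empty clusters are allowed and keep their
centroid. Because under exact convergence the loss is non-increasing in
k, the small iteration budget is what keeps the argmin away from the
degenerate k = n collapse; this is inherently heuristic, and a
``penalized`` mode (loss + gamma * non-empty clusters) is provided as a
stabler alternative.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.morphology import skeletonize as _skimage_skeletonize

from .preprocess import BinaryFeatureImage

__all__ = [
    "SkeletonImage",
    "EndpointSet",
    "ClusterSolution",
    "skeletonize",
    "detect_endpoints",
    "kmeans_fit",
    "select_cluster_count",
    "count_follicles",
]


@dataclass(frozen=True)
class SkeletonImage:
    """One-pixel-wide thinning of a feature mask."""

    mask: np.ndarray

    @property
    def side(self) -> int:
        return self.mask.shape[0]


@dataclass(frozen=True)
class EndpointSet:
    """Skeleton endpoints as (x, y) in [0,1]^2 plus original pixel coords."""

    points: np.ndarray        # (n, 2) float, columns (x, y) standardized by side
    pixel_coords: np.ndarray  # (n, 2) int, columns (row, col)
    side: int

    def __len__(self) -> int:
        return len(self.points)


@dataclass(frozen=True)
class ClusterSolution:
    """A K-means fit: requested k, centroids, assignments, SSE loss.

    ``nonempty`` counts clusters holding at least one point — the
    follicle count. ``loss_trace`` holds the per-iteration loss (after
    each centroid update) for diagnostics.
    """

    k: int
    centroids: np.ndarray
    assignments: np.ndarray
    loss: float
    nonempty: int
    seed: int
    loss_trace: tuple[float, ...] = field(default=(), compare=False)


def skeletonize(mask: BinaryFeatureImage | np.ndarray) -> SkeletonImage:
    """Topology-preserving thinning to 1-px-wide center lines."""
    m = mask.mask if isinstance(mask, BinaryFeatureImage) else np.asarray(mask, dtype=bool)
    return SkeletonImage(mask=_skimage_skeletonize(m))


_NEIGHBOR_KERNEL = np.array([[1, 1, 1], [1, 0, 1], [1, 1, 1]], dtype=np.uint8)


def detect_endpoints(skel: SkeletonImage | np.ndarray) -> EndpointSet:
    """Skeleton pixels with exactly one true 8-neighbor.

    Isolated pixels (zero neighbors) are not endpoints. Coordinates are
    standardized to [0, 1] by dividing by the image side; x is the
    column coordinate, y the row coordinate.
    """
    m = skel.mask if isinstance(skel, SkeletonImage) else np.asarray(skel, dtype=bool)
    nbrs = ndimage.convolve(m.astype(np.uint8), _NEIGHBOR_KERNEL, mode="constant", cval=0)
    ep = m & (nbrs == 1)
    rc = np.argwhere(ep)
    side = m.shape[0]
    pts = np.column_stack([rc[:, 1], rc[:, 0]]).astype(float) / side if len(rc) else np.empty((0, 2))
    return EndpointSet(points=pts, pixel_coords=rc, side=side)


def _sse(pts: np.ndarray, centroids: np.ndarray, assign: np.ndarray) -> float:
    if len(pts) == 0:
        return 0.0
    return float(((pts - centroids[assign]) ** 2).sum())


def kmeans_fit(points: EndpointSet | np.ndarray, k: int, rng_seed: int = 0, max_iter: int = 10) -> ClusterSolution:
    """Lloyd's algorithm from a clipped-Gaussian initialization.

    Centroids are drawn i.i.d. per axis from N(0.5, 0.25^2) clipped to
    [0, 1]. Empty clusters keep their centroid (no re-seeding). Stops
    when assignments stabilize or after ``max_iter`` sweeps; the
    reported loss is recomputed from the final assignments.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    pts = points.points if isinstance(points, EndpointSet) else np.asarray(points, dtype=float)
    rng = np.random.default_rng(rng_seed)
    centroids = np.clip(rng.normal(0.5, 0.25, size=(k, 2)), 0.0, 1.0)

    if len(pts) == 0:
        return ClusterSolution(k=k, centroids=centroids, assignments=np.empty(0, dtype=int),
                               loss=0.0, nonempty=0, seed=rng_seed)

    trace: list[float] = []
    prev = None
    for _ in range(max_iter):
        d2 = ((pts[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
        assign = d2.argmin(axis=1)
        for j in np.unique(assign):
            centroids[j] = pts[assign == j].mean(axis=0)
        trace.append(_sse(pts, centroids, assign))
        if prev is not None and np.array_equal(assign, prev):
            break
        prev = assign

    # final assignment against the settled centroids
    d2 = ((pts[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
    assign = d2.argmin(axis=1)
    return ClusterSolution(
        k=k,
        centroids=centroids,
        assignments=assign,
        loss=_sse(pts, centroids, assign),
        nonempty=int(len(np.unique(assign))),
        seed=rng_seed,
        loss_trace=tuple(trace),
    )


def select_cluster_count(
    points: EndpointSet | np.ndarray,
    rng_seed: int = 0,
    max_iter: int = 10,
    selection: str = "min_loss",
    gamma: float = 0.01,
) -> ClusterSolution:
    """Sweep k = 1..n and keep the best solution.

    ``min_loss`` mode returns the minimum-loss solution (ties toward
    smaller k); ``penalized`` minimizes loss + gamma * nonempty, which
    trades a small per-cluster charge against the SSE and is stable for
    well-separated endpoint groups. Each k is seeded as rng_seed + k so
    the sweep is reproducible and the fits independent.
    """
    if selection not in ("min_loss", "penalized"):
        raise ValueError("selection must be 'min_loss' or 'penalized'")
    pts = points.points if isinstance(points, EndpointSet) else np.asarray(points, dtype=float)
    n = len(pts)
    if n == 0:
        return ClusterSolution(k=0, centroids=np.empty((0, 2)), assignments=np.empty(0, dtype=int),
                               loss=0.0, nonempty=0, seed=rng_seed)

    best: ClusterSolution | None = None
    best_obj = np.inf
    for k in range(1, n + 1):
        sol = kmeans_fit(pts, k, rng_seed=rng_seed + k, max_iter=max_iter)
        obj = sol.loss if selection == "min_loss" else sol.loss + gamma * sol.nonempty
        if obj < best_obj - 1e-15:  # strict improvement only: ties keep smaller k
            best, best_obj = sol, obj
    assert best is not None
    return best


def count_follicles(sol: ClusterSolution) -> int:
    """Follicle count = number of non-empty clusters."""
    return sol.nonempty
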