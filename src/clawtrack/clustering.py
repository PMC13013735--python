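"""Density-based clustering of motion points into individual crabs.

Each frame's above-threshold grid cells form a sparse point set; DBSCAN
groups nearby points into clusters that are treated as one individual, with
no preset cluster count — exactly what field scenes with varying numbers of
crabs need. Cluster centroids are what the tracker matches across frames.

DBSCAN is implemented here rather than delegated, with classic semantics:

* a *core point* has at least ``min_pts`` neighbors within ``eps``
  (the point itself counts — library conventions differ on this);
* clusters grow by density-reachability from core points;
* points reachable from no core point are noise (label ``-1``);
* a border point reachable from several clusters joins the first cluster
  (in point-index order) that reaches it. Point order is fixed to row-major
  grid order upstream, so results are reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

__all__ = ["NOISE", "MotionPointSet", "ClusterSet", "dbscan", "cluster_centroids"]

#: Label assigned to points that belong to no cluster.
NOISE = -1


@dataclass
class MotionPointSet:
    """Nonzero grid cells of one frame: positions, vectors, and speeds."""

    points: np.ndarray  # (n, 2) pixel (x, y)
    velocities: np.ndarray  # (n, 2) px/frame (u, v)

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, dtype=np.float64))
        self.velocities = np.atleast_2d(np.asarray(self.velocities, dtype=np.float64))
        if self.points.size == 0:
            self.points = self.points.reshape(0, 2)
            self.velocities = self.velocities.reshape(0, 2)
        if self.points.shape != self.velocities.shape or self.points.shape[1] != 2:
            raise ValueError("points and velocities must both be (n, 2)")

    @classmethod
    def from_grid(cls, grid) -> "MotionPointSet":
        """Collect nonzero cells of a thresholded grid in row-major order."""
        mask = grid.cell_speed > 0
        pts = np.column_stack([grid.cell_x[mask], grid.cell_y[mask]])
        vel = np.column_stack([grid.cell_u[mask], grid.cell_v[mask]])
        return cls(points=pts, velocities=vel)

    @property
    def speeds(self) -> np.ndarray:
        return np.hypot(self.velocities[:, 0], self.velocities[:, 1])

    def __len__(self) -> int:
        return len(self.points)


@dataclass
class ClusterSet:
    """DBSCAN output for one frame.

    ``labels`` aligns with the input points (``NOISE`` = -1); clusters are
    numbered 0..k-1 in order of discovery. ``centroids`` are per-cluster mean
    positions, ``mean_speeds`` per-cluster mean cell speeds — the quantity
    tracked over time as the claw-wave signal.
    """

    labels: np.ndarray
    centroids: np.ndarray  # (k, 2)
    sizes: np.ndarray  # (k,)
    mean_speeds: np.ndarray  # (k,)

    @property
    def n_clusters(self) -> int:
        return len(self.centroids)


def dbscan(points: MotionPointSet | np.ndarray, eps: float, min_pts: int) -> np.ndarray:
    """Label points with DBSCAN under Euclidean distance.

    Returns an integer label per point; ``NOISE`` marks unclustered points.
    An empty input yields an empty label array.
    """
    if not eps > 0:
        raise ValueError(f"eps must be positive, got {eps}")
    if min_pts < 1:
        raise ValueError(f"min_pts must be >= 1, got {min_pts}")
    pts = points.points if isinstance(points, MotionPointSet) else np.asarray(points, float)
    n = len(pts)
    labels = np.full(n, NOISE, dtype=np.int64)
    if n == 0:
        return labels

    tree = cKDTree(pts)
    neighborhoods = tree.query_ball_point(pts, r=eps)  # includes the point itself
    is_core = np.array([len(nb) >= min_pts for nb in neighborhoods])

    cluster = 0
    for i in range(n):
        if labels[i] != NOISE or not is_core[i]:
            continue
        # BFS over density-reachable points from this seed core point.
        labels[i] = cluster
        frontier = [i]
        while frontier:
            j = frontier.pop()
            if not is_core[j]:
                continue
            for k in sorted(neighborhoods[j]):
                if labels[k] == NOISE:
                    labels[k] = cluster
                    frontier.append(k)
        cluster += 1
    return labels


def cluster_centroids(points: MotionPointSet, labels: np.ndarray) -> ClusterSet:
    """Reduce labeled points to per-cluster centroid, size, and mean speed.

    The centroid is the arithmetic mean of member positions; noise points are
    excluded. Every non-noise cluster is nonempty by construction.
    """
    labels = np.asarray(labels)
    if len(labels) != len(points):
        raise ValueError(f"{len(labels)} labels for {len(points)} points")
    ids = np.unique(labels[labels != NOISE])
    centroids = np.empty((len(ids), 2))
    sizes = np.empty(len(ids), dtype=np.int64)
    speeds = np.empty(len(ids))
    pt_speed = points.speeds
    for row, cid in enumerate(ids):
        member = labels == cid
        centroids[row] = points.points[member].mean(axis=0)
        sizes[row] = member.sum()
        speeds[row] = pt_speed[member].mean()
    return ClusterSet(labels=labels, centroids=centroids, sizes=sizes, mean_speeds=speeds)
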