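"""Independent brute-force references used only by the test suite."""

from __future__ import annotations

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

NOISE = -1


def brute_force_dbscan(points: np.ndarray, eps: float, min_pts: int) -> np.ndarray:
    """Reference DBSCAN via an exhaustive neighbor graph.

    Formulated differently from the implementation under test: core points
    are read off the full pairwise distance matrix, clusters are the
    connected components of the core-core adjacency graph, and border
    points join the component, among their core neighbors', whose earliest
    (lowest-index) core point comes first — the same deterministic
    border-assignment rule, reached by a different route.
    """
    points = np.asarray(points, dtype=np.float64)
    n = len(points)
    labels = np.full(n, NOISE, dtype=np.int64)
    if n == 0:
        return labels
    d = np.linalg.norm(points[:, None, :] - points[None, :, :], axis=2)
    adj = d <= eps  # includes self
    core = adj.sum(axis=1) >= min_pts
    core_idx = np.nonzero(core)[0]
    if len(core_idx) == 0:
        return labels

    core_adj = csr_matrix(adj[np.ix_(core_idx, core_idx)])
    n_comp, comp = connected_components(core_adj, directed=False)
    # order components by their lowest core-point index = discovery order
    first_idx = np.array([core_idx[comp == c].min() for c in range(n_comp)])
    rank = np.argsort(np.argsort(first_idx))
    labels[core_idx] = rank[comp]

    for i in np.nonzero(~core)[0]:
        reach = [labels[j] for j in core_idx if adj[i, j]]
        if reach:
            labels[i] = min(reach)
    return labels


def partitions_equal(labels_a: np.ndarray, labels_b: np.ndarray) -> bool:
    """Same clustering up to label permutation, with noise matched exactly."""
    labels_a, labels_b = np.asarray(labels_a), np.asarray(labels_b)
    if labels_a.shape != labels_b.shape:
        return False
    if not np.array_equal(labels_a == NOISE, labels_b == NOISE):
        return False
    mapping: dict[int, int] = {}
    seen: set[int] = set()
    for a, b in zip(labels_a, labels_b):
        if a == NOISE:
            continue
        if a in mapping:
            if mapping[a] != b:
                return False
        else:
            if b in seen:
                return False
            mapping[a] = b
            seen.add(b)
    return True


def greedy_match_reference(
    rows: np.ndarray, cols: np.ndarray, max_dist: float
) -> list[tuple[int, int]]:
    """Greedy globally-smallest-distance matching by repeated full scans."""
    rows = np.asarray(rows, dtype=np.float64).reshape(-1, 2)
    cols = np.asarray(cols, dtype=np.float64).reshape(-1, 2)
    free_r = set(range(len(rows)))
    free_c = set(range(len(cols)))
    pairs: list[tuple[int, int]] = []
    while free_r and free_c:
        best = None
        for i in sorted(free_r):
            for j in sorted(free_c):
                dij = float(np.linalg.norm(rows[i] - cols[j]))
                if dij > max_dist:
                    continue
                if best is None or dij < best[0]:
                    best = (dij, i, j)
        if best is None:
            break
        _, i, j = best
        pairs.append((i, j))
        free_r.remove(i)
        free_c.remove(j)
    return pairs
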