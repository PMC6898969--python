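"""Average-linkage hierarchical clustering with uncentered Pearson distance.

The distance between two expression profiles x, y is 1 - r_u where

    r_u(x, y) = sum(x_i y_i) / sqrt(sum(x_i^2) * sum(y_i^2))

(the uncentered correlation, i.e. cosine similarity).  Agglomeration uses
unweighted average linkage (UPGMA) with a deterministic tie-break: among
pairs at the minimal distance, the pair with the lowest cluster indices is
merged first.  Cluster indices follow the usual convention: original rows
are 0..n-1 and the cluster formed at merge step k gets index n + k.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import ValidationError

__all__ = ["Dendrogram", "uncentered_correlation", "uncentered_distance_matrix",
           "hierarchical_cluster"]


@dataclass
class Dendrogram:
    """Merge sequence and derived leaf order for one clustering run.

    ``merges`` has one row per agglomeration step: (index_i, index_j, height,
    new_cluster_size) with index_i < index_j.  Heights are non-decreasing.
    """

    merges: np.ndarray
    leaf_order: list[int]
    labels: list[str]

    @property
    def ordered_labels(self) -> list[str]:
        return [self.labels[i] for i in self.leaf_order]


def uncentered_correlation(x: np.ndarray, y: np.ndarray) -> float:
    """Cosine similarity of two profiles (undefined for all-zero input)."""
    nx = float(np.sqrt(np.sum(np.square(x))))
    ny = float(np.sqrt(np.sum(np.square(y))))
    if nx == 0.0 or ny == 0.0:
        raise ValidationError("uncentered correlation undefined for an all-zero row")
    return float(np.dot(x, y) / (nx * ny))


def uncentered_distance_matrix(rows: np.ndarray, labels: list[str]) -> np.ndarray:
    norms = np.sqrt(np.sum(np.square(rows), axis=1))
    zero = np.flatnonzero(norms == 0.0)
    if zero.size:
        raise ValidationError(
            f"all-zero row {labels[zero[0]]!r}: uncentered correlation undefined"
        )
    sim = (rows @ rows.T) / np.outer(norms, norms)
    dist = 1.0 - sim
    np.fill_diagonal(dist, np.inf)
    # proportional rows have similarity 1 up to rounding; snap to exactly 0
    dist[np.abs(dist) < 1e-12] = 0.0
    return dist


def hierarchical_cluster(
    rows: np.ndarray, labels: list[str] | None = None
) -> Dendrogram:
    """Cluster profile rows by average linkage on uncentered-Pearson distance.

    Suitable for up to a few thousand rows (the agglomeration is O(n^3) in
    the worst case but vectorised per step).
    """
    rows = np.asarray(rows, dtype=float)
    if rows.ndim != 2 or rows.shape[0] < 2:
        raise ValidationError("need a 2-D array with at least 2 rows")
    n = rows.shape[0]
    if labels is None:
        labels = [str(i) for i in range(n)]
    if len(labels) != n:
        raise ValidationError("labels length must match number of rows")

    dist = uncentered_distance_matrix(rows, labels)
    # position p in the working matrix <-> cluster id ids[p]
    ids = list(range(n))
    sizes = {i: 1 for i in range(n)}
    children: dict[int, tuple[int, int]] = {}
    merges = np.empty((n - 1, 4), dtype=float)

    for step in range(n - 1):
        # first occurrence of the minimum in row-major order gives the
        # lowest-index pair (ids are appended in increasing order, so working
        # positions are ordered by cluster id)
        flat = np.argmin(dist)
        pi, pj = divmod(int(flat), dist.shape[0])
        if pi > pj:
            pi, pj = pj, pi
        height = float(dist[pi, pj])
        ci, cj = ids[pi], ids[pj]
        new_id = n + step
        new_size = sizes[ci] + sizes[cj]
        merges[step] = (ci, cj, height, new_size)
        children[new_id] = (ci, cj)

        # Lance-Williams update for unweighted average linkage
        new_row = (sizes[ci] * dist[pi, :] + sizes[cj] * dist[pj, :]) / new_size
        keep = np.ones(dist.shape[0], dtype=bool)
        keep[[pi, pj]] = False
        new_row = new_row[keep]
        dist = dist[np.ix_(keep, keep)]
        dist = np.pad(dist, ((0, 1), (0, 1)), constant_values=np.inf)
        dist[-1, :-1] = new_row
        dist[:-1, -1] = new_row
        dist[-1, -1] = np.inf

        ids = [c for c in ids if c not in (ci, cj)] + [new_id]
        sizes[new_id] = new_size

    # iterative depth-first traversal (left child first) for the leaf order
    leaf_order: list[int] = []
    stack = [2 * n - 2]
    while stack:
        cluster = stack.pop()
        if cluster < n:
            leaf_order.append(cluster)
        else:
            left, right = children[cluster]
            stack.append(right)
            stack.append(left)
    return Dendrogram(merges=merges, leaf_order=leaf_order, labels=list(labels))
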