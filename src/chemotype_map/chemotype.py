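"""Bray-Curtis resemblance and group-average (UPGMA) chemogrouping.

Samples with similar secondary-metabolite profiles are grouped by computing
pairwise Bray-Curtis dissimilarity on the base-peak-relative feature matrix,
clustering with unweighted group-average linkage, and cutting the dendrogram
at a similarity threshold (50% by default): each maximal subtree whose
internal merges all exceed the threshold similarity becomes a chemogroup.

The linkage is implemented directly so that tie-breaking between equal-height
merges is fully deterministic (smallest leaf indices win), which makes the
dendrogram invariant to sample input order; the merge list uses the same
(node_a, node_b, height, size) convention as :mod:`scipy.cluster.hierarchy`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ChemotypeError",
    "bray_curtis",
    "similarity_pct",
    "resemblance_matrix",
    "Dendrogram",
    "upgma",
    "cut_dendrogram",
    "dendrogram_newick",
]


class ChemotypeError(ValueError):
    """Raised for invalid abundance vectors or resemblance matrices."""


def bray_curtis(x, y) -> float:
    """Bray-Curtis dissimilarity sum|x-y| / sum(x+y) in [0, 1].

    Both vectors must be non-negative and of equal length; a pair of all-zero
    vectors is undefined.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ChemotypeError("abundance vectors must be 1-D and of equal length")
    if np.any(x < 0) or np.any(y < 0):
        raise ChemotypeError("abundances must be non-negative")
    denom = float(np.sum(x + y))
    if denom == 0:
        raise ChemotypeError("Bray-Curtis is undefined for two all-zero vectors")
    return float(np.sum(np.abs(x - y)) / denom)


def similarity_pct(d) -> np.ndarray | float:
    """Similarity view of a Bray-Curtis dissimilarity: 100 * (1 - d)."""
    return 100.0 * (1.0 - np.asarray(d, dtype=float)) if np.ndim(d) else 100.0 * (1.0 - d)


def resemblance_matrix(table: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Bray-Curtis dissimilarity between the rows of a feature table."""
    values = table.to_numpy(dtype=float)
    if np.any(values.sum(axis=1) == 0):
        empty = table.index[values.sum(axis=1) == 0].tolist()
        raise ChemotypeError(f"samples with no retained features: {empty}")
    n = values.shape[0]
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = bray_curtis(values[i], values[j])
    return pd.DataFrame(d, index=table.index, columns=table.index)


@dataclass
class Dendrogram:
    """Group-average merge tree over named leaves.

    ``merges`` is an (n-1, 4) array of (node_a, node_b, height, size) rows in
    scipy linkage convention: leaves are nodes 0..n-1 in ``ids`` order, the
    i-th merge creates node n+i.  Heights are Bray-Curtis dissimilarities.
    """

    ids: list[str]
    merges: np.ndarray

    @property
    def n_leaves(self) -> int:
        return len(self.ids)

    def to_linkage(self) -> np.ndarray:
        """The merge list as a scipy-compatible linkage matrix (float copy)."""
        return np.asarray(self.merges, dtype=float).copy()


def _validate_square(matrix: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    d = matrix.to_numpy(dtype=float)
    ids = [str(i) for i in matrix.index]
    if d.shape[0] != d.shape[1] or list(matrix.columns.astype(str)) != ids:
        raise ChemotypeError("resemblance matrix must be square with matching labels")
    if not np.allclose(d, d.T, atol=1e-12):
        raise ChemotypeError("resemblance matrix must be symmetric")
    if np.any(np.diag(d) != 0):
        raise ChemotypeError("resemblance matrix must have a zero diagonal")
    if np.any(d < 0) or np.any(d > 1):
        raise ChemotypeError("Bray-Curtis dissimilarities must lie in [0, 1]")
    return d, ids


def upgma(matrix: pd.DataFrame) -> Dendrogram:
    """Unweighted group-average agglomerative clustering of a dissimilarity matrix.

    At each step the pair of clusters with the smallest mean between-cluster
    dissimilarity is merged at that mean height; between-cluster means to the
    new cluster are updated with leaf-count weights (UPGMA proper).  Ties are
    broken by the lexicographically smallest (min leaf index, max leaf index,
    sorted leaf tuple) of the merged pair.
    """
    d, ids = _validate_square(matrix)
    n = len(ids)
    if n < 2:
        raise ChemotypeError("need at least two samples to cluster")

    # cluster id -> (sorted leaf tuple, scipy node id)
    active: dict[int, tuple[tuple[int, ...], int]] = {i: ((i,), i) for i in range(n)}
    dist: dict[frozenset[int], float] = {
        frozenset((i, j)): float(d[i, j]) for i in range(n) for j in range(i + 1, n)
    }
    merges = np.zeros((n - 1, 4))
    next_node = n
    for step in range(n - 1):
        best_key = None
        best_pair = None
        for pair, dv in dist.items():
            a, b = sorted(pair)
            leaves = tuple(sorted(active[a][0] + active[b][0]))
            key = (dv, leaves[0], leaves[-1], leaves)
            if best_key is None or key < best_key:
                best_key, best_pair = key, (a, b)
        a, b = best_pair
        height = dist.pop(frozenset((a, b)))
        la, na = active[a][0], len(active[a][0])
        lb, nb = active[b][0], len(active[b][0])
        node_a, node_b = active[a][1], active[b][1]
        new_id = min(a, b)
        for c in list(active):
            if c in (a, b):
                continue
            da = dist.pop(frozenset((a, c)))
            db = dist.pop(frozenset((b, c)))
            dist[frozenset((new_id, c))] = (na * da + nb * db) / (na + nb)
        del active[max(a, b)]
        active[new_id] = (tuple(sorted(la + lb)), next_node)
        merges[step] = (min(node_a, node_b), max(node_a, node_b), height, na + nb)
        next_node += 1
    return Dendrogram(ids=ids, merges=merges)


def cut_dendrogram(dend: Dendrogram, similarity_pct: float = 50.0) -> dict[str, str]:
    """Assign chemogroup labels by cutting the dendrogram at a similarity level.

    Clusters are the maximal subtrees whose internal merge heights are all
    strictly below ``1 - similarity_pct/100`` — i.e. groups of samples joined
    at more than ``similarity_pct`` percent similarity.  Labels CG1..CGk are
    numbered by order of first appearance in the leaf id list.
    """
    if not (0 <= similarity_pct <= 100):
        raise ChemotypeError("similarity_pct must lie in [0, 100]")
    cutoff = 1.0 - similarity_pct / 100.0
    n = dend.n_leaves
    parent = list(range(2 * n - 1))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for step, (a, b, height, _) in enumerate(dend.merges):
        if height < cutoff:
            node = n + step
            parent[find(int(a))] = node
            parent[find(int(b))] = node

    labels: dict[str, str] = {}
    root_label: dict[int, str] = {}
    for i, sid in enumerate(dend.ids):
        root = find(i)
        if root not in root_label:
            root_label[root] = f"CG{len(root_label) + 1}"
        labels[sid] = root_label[root]
    return labels


def dendrogram_newick(dend: Dendrogram) -> str:
    """Newick rendering with branch lengths equal to merge-height differences."""
    n = dend.n_leaves
    height = {i: 0.0 for i in range(n)}
    children: dict[int, tuple[int, int]] = {}
    for step, (a, b, h, _) in enumerate(dend.merges):
        node = n + step
        height[node] = float(h)
        children[node] = (int(a), int(b))

    def render(node: int, parent_height: float) -> str:
        bl = parent_height - height[node]
        if node < n:
            return f"{dend.ids[node]}:{bl:.6f}"
        a, b = children[node]
        inner = ",".join(render(c, height[node]) for c in (a, b))
        return f"({inner}):{bl:.6f}"

    root = n + len(dend.merges) - 1 if len(dend.merges) else 0
    if root < n:
        return f"{dend.ids[root]};"
    a, b = children[root]
    inner = ",".join(render(c, height[root]) for c in (a, b))
    return f"({inner});"
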