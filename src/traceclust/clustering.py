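"""Complete-linkage agglomerative clustering on a precomputed dissimilarity.

The agglomerator starts from singleton clusters and repeatedly merges the
two clusters at minimal dissimilarity, where the dissimilarity between two
clusters is the *maximum* pairwise dissimilarity between their members
(complete linkage).  Complete linkage guarantees non-decreasing merge
heights on any dissimilarity input, so no metric assumption is needed —
which matters here because the activity-weighted JS dissimilarity is not a
metric.

Tie-break: when several pairs attain the minimal dissimilarity, the pair
with the lexicographically smallest cluster ids is merged (leaves are
0..n-1 in input order; the cluster created by merge m gets id n+m).  This
makes results bit-reproducible across runs and platforms.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from traceclust.dissimilarity import DissimilarityMatrix
from traceclust.errors import ConfigurationError


@dataclass
class Dendrogram:
    """Merge history of an agglomerative clustering.

    ``merges[m] = (a, b, height)`` with a < b cluster ids; leaves are ids
    0..n_leaves-1, merge m creates id n_leaves+m.
    """

    merges: list[tuple[int, int, float]]
    n_leaves: int
    leaf_names: list[str]

    def to_linkage_matrix(self) -> np.ndarray:
        """SciPy-style (n-1, 4) linkage matrix (for plotting interop)."""
        sizes = {i: 1 for i in range(self.n_leaves)}
        Z = np.zeros((len(self.merges), 4))
        for m, (a, b, h) in enumerate(self.merges):
            size = sizes[a] + sizes[b]
            sizes[self.n_leaves + m] = size
            Z[m] = [a, b, h, size]
        return Z

    def to_newick(self) -> str:
        """Newick text with branch lengths from merge heights (leaf height 0)."""
        height = {i: 0.0 for i in range(self.n_leaves)}
        node: dict[int, str] = {
            i: name for i, name in enumerate(self.leaf_names)
        }
        root = self.n_leaves - 1 if not self.merges else 0
        for m, (a, b, h) in enumerate(self.merges):
            la = h - height[a]
            lb = h - height[b]
            nid = self.n_leaves + m
            node[nid] = f"({node[a]}:{la:.10g},{node[b]}:{lb:.10g})"
            height[nid] = h
            root = nid
        return node[root] + ";"


@dataclass
class ClusterResult:
    """A flat clustering: actor id -> cluster label in 1..k."""

    labels: dict[str, int]
    k: int
    height_threshold: float | None = None

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {"actor_id": list(self.labels), "cluster": list(self.labels.values())}
        ).to_csv(path, index=False)

    def label_array(self, actor_ids: list[str]) -> np.ndarray:
        return np.array([self.labels[a] for a in actor_ids])


def _check_matrix(D: np.ndarray) -> None:
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ConfigurationError("dissimilarity matrix must be square")
    if not np.allclose(D, D.T, atol=1e-12):
        raise ConfigurationError("dissimilarity matrix must be symmetric")
    if not np.allclose(np.diag(D), 0.0, atol=1e-12):
        raise ConfigurationError("dissimilarity matrix must have zero diagonal")


def complete_linkage(matrix: DissimilarityMatrix | np.ndarray) -> Dendrogram:
    """Complete-linkage merge sequence with the lexicographic tie-break."""
    if isinstance(matrix, DissimilarityMatrix):
        D = np.asarray(matrix.D, dtype=float)
        names = list(matrix.actor_ids)
    else:
        D = np.asarray(matrix, dtype=float)
        names = [str(i) for i in range(D.shape[0])]
    _check_matrix(D)
    n = D.shape[0]
    if n < 2:
        raise ConfigurationError("need at least two points to cluster")

    # dist maps active cluster id -> {other active id -> complete-linkage dist}
    active: list[int] = list(range(n))
    dist = {i: {j: D[i, j] for j in range(n) if j != i} for i in range(n)}
    merges: list[tuple[int, int, float]] = []
    next_id = n
    for _ in range(n - 1):
        best = None
        for ai, a in enumerate(active):
            for b in active[ai + 1 :]:
                d = dist[a][b]
                if best is None or d < best[0] or (d == best[0] and (a, b) < best[1:]):
                    best = (d, a, b)
        d, a, b = best
        merges.append((a, b, d))
        new_dist = {}
        for c in active:
            if c in (a, b):
                continue
            new_dist[c] = max(dist[a][c], dist[b][c])
            del dist[c][a]
            del dist[c][b]
            dist[c][next_id] = new_dist[c]
        del dist[a], dist[b]
        dist[next_id] = new_dist
        active = [c for c in active if c not in (a, b)] + [next_id]
        next_id += 1
    return Dendrogram(merges=merges, n_leaves=n, leaf_names=names)


def cut(
    dendrogram: Dendrogram, k: int | None = None, height: float | None = None
) -> ClusterResult:
    """Flat clusters from a dendrogram, by cluster count or merge height.

    By count: the first n-k merges are applied, yielding exactly k
    clusters.  By height: all merges at height <= the threshold are
    applied, so clusters separated strictly above the threshold remain
    apart.  Labels are 1..k in order of each cluster's first leaf.
    """
    if (k is None) == (height is None):
        raise ConfigurationError("specify exactly one of k or height")
    n = dendrogram.n_leaves
    if k is not None and not 1 <= k <= n:
        raise ConfigurationError(f"k must be in 1..{n}")
    parent = list(range(n + len(dendrogram.merges)))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    n_apply = n - k if k is not None else None
    for m, (a, b, h) in enumerate(dendrogram.merges):
        if n_apply is not None and m >= n_apply:
            break
        if height is not None and h > height:
            continue
        nid = n + m
        parent[find(a)] = nid
        parent[find(b)] = nid

    label_of_root: dict[int, int] = {}
    labels: dict[str, int] = {}
    for leaf in range(n):
        root = find(leaf)
        if root not in label_of_root:
            label_of_root[root] = len(label_of_root) + 1
        labels[dendrogram.leaf_names[leaf]] = label_of_root[root]
    return ClusterResult(
        labels=labels, k=len(label_of_root), height_threshold=height
    )


def silhouette_report(
    matrix: DissimilarityMatrix, k_range=range(2, 11)
) -> pd.DataFrame:
    """Silhouette score per candidate k — a diagnostic, never an auto-selector."""
    from sklearn.metrics import silhouette_score

    dendro = complete_linkage(matrix)
    rows = []
    for k in k_range:
        if not 2 <= k < dendro.n_leaves:
            continue
        res = cut(dendro, k=k)
        rows.append(
            {
                "k": k,
                "silhouette": float(
                    silhouette_score(
                        matrix.D,
                        res.label_array(matrix.actor_ids),
                        metric="precomputed",
                    )
                ),
            }
        )
    return pd.DataFrame(rows)
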