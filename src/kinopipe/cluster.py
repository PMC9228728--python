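"""Hierarchical clustering of arrays and peptides for the two-way heatmap.

Distance is 1 - Pearson correlation across features; linkage is WPGMA
(McQuitty): when clusters u and v merge, the distance from the merged
cluster to any other cluster k is the plain average
``(d(u,k) + d(v,k)) / 2``, regardless of cluster sizes.  Ties in the
minimum-distance search are broken by the lexicographically smallest pair of
cluster indices (clusters indexed by creation order, leaves first), which
makes the merge sequence deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["Dendrogram", "pearson_distance_matrix", "wpgma_cluster",
           "heatmap_export"]


@dataclass(frozen=True)
class Dendrogram:
    """Binary merge tree over named leaves.

    ``merges[j] = (left, right, height)`` creates internal node
    ``n_leaves + j`` from existing node indices; leaves are 0..n_leaves-1 in
    the order of ``labels``.
    """

    labels: tuple[str, ...]
    merges: tuple[tuple[int, int, float], ...]

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    @property
    def heights(self) -> tuple[float, ...]:
        return tuple(h for _, _, h in self.merges)

    def leaf_order(self) -> list[str]:
        """Left-to-right leaf order implied by the merge structure."""
        n = self.n_leaves

        def walk(node: int) -> list[int]:
            if node < n:
                return [node]
            left, right, _ = self.merges[node - n]
            return walk(left) + walk(right)

        root = n + len(self.merges) - 1 if self.merges else 0
        return [self.labels[i] for i in walk(root)]

    def to_newick(self) -> str:
        """Serialize as a Newick string with branch lengths derived from
        merge heights (leaf branch length = height/2 of its first merge)."""
        n = self.n_leaves
        height = {i: 0.0 for i in range(n)}

        def name(node: int) -> str:
            if node < n:
                lbl = self.labels[node]
                for ch in "(),:;'\t\n ":
                    lbl = lbl.replace(ch, "_")
                return lbl
            left, right, h = self.merges[node - n]
            parts = []
            for child in (left, right):
                child_str = name(child)  # sets height[child] for internal nodes
                # ultrametric convention: leaf-to-node path length = height/2
                bl = (h - height[child]) / 2.0
                parts.append(f"{child_str}:{max(bl, 0.0):.10g}")
            height[node] = h
            return "(" + ",".join(parts) + ")"

        if not self.merges:
            return f"{name(0)};"
        return name(n + len(self.merges) - 1) + ";"


def pearson_distance_matrix(profiles: pd.DataFrame) -> pd.DataFrame:
    """Pairwise ``1 - Pearson r`` distances between the rows of a
    (items x features) frame.  Range [0, 2], zero diagonal, symmetric."""
    mat = profiles.to_numpy(float)
    if mat.shape[0] < 2:
        raise ValueError("need at least 2 items")
    sd = mat.std(axis=1)
    flat = np.flatnonzero(sd == 0)
    if flat.size:
        raise ValueError(
            f"zero variance across features for item(s): "
            f"{[profiles.index[i] for i in flat[:5]]}"
        )
    r = np.corrcoef(mat)
    d = 1.0 - r
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2.0, 0.0, 2.0)
    return pd.DataFrame(d, index=profiles.index, columns=profiles.index)


def wpgma_cluster(dist: pd.DataFrame) -> Dendrogram:
    """Agglomerative WPGMA clustering of a symmetric distance matrix.

    Naive O(n^3) search is adequate at array/peptide scale and keeps the
    lexicographic tie-break explicit; cross-checked against
    ``scipy.cluster.hierarchy.linkage(method="weighted")`` in the test suite.
    """
    d = dist.to_numpy(float).copy()
    if d.shape[0] != d.shape[1] or d.shape[0] < 2:
        raise ValueError("distance matrix must be square with n >= 2")
    if np.isnan(d).any():
        raise ValueError("distance matrix contains NaN")

    labels = tuple(str(i) for i in dist.index)
    n = len(labels)
    # active maps current matrix row -> dendrogram node index
    node_of = list(range(n))
    active = list(range(n))
    merges: list[tuple[int, int, float]] = []
    for step in range(n - 1):
        best = None
        for ai in range(len(active)):
            for aj in range(ai + 1, len(active)):
                i, j = active[ai], active[aj]
                lo, hi = sorted((node_of[i], node_of[j]))
                key = (d[i, j], lo, hi)
                if best is None or key < best[0]:
                    best = (key, ai, aj)
        (h, lo, hi), ai, aj = best
        i, j = active[ai], active[aj]
        merges.append((lo, hi, float(h)))
        # WPGMA update into slot i
        for k in active:
            if k not in (i, j):
                d[i, k] = d[k, i] = (d[i, k] + d[j, k]) / 2.0
        node_of[i] = n + step
        active.pop(aj)
    return Dendrogram(labels=labels, merges=tuple(merges))


def heatmap_export(profiles: pd.DataFrame, row_dendrogram: Dendrogram,
                   col_dendrogram: Dendrogram) -> dict:
    """Permute a (rows x cols) matrix to dendrogram leaf orders for heatmap
    serialization.  Returns the ordered matrix plus both trees as Newick."""
    row_order = row_dendrogram.leaf_order()
    col_order = col_dendrogram.leaf_order()
    if set(row_order) != set(map(str, profiles.index)) or len(row_order) != len(profiles.index):
        raise ValueError("row dendrogram leaves do not match matrix rows")
    if set(col_order) != set(map(str, profiles.columns)) or len(col_order) != len(profiles.columns):
        raise ValueError("column dendrogram leaves do not match matrix columns")
    ordered = profiles.loc[row_order, col_order]
    return {
        "matrix": ordered,
        "row_newick": row_dendrogram.to_newick(),
        "col_newick": col_dendrogram.to_newick(),
    }
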