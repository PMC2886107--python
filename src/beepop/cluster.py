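"""Self-organizing tree (SOTA) clustering of P-value profiles and dendrograms.

SOTA grows a binary tree divisively: starting from one cell holding every
profile, each cycle splits the leaf with the greatest *diversity* (mean
Euclidean distance of its members to the cell centroid) into two daughter
cells, then runs adaptation epochs in which each member of the split cell
migrates to its nearest daughter while the winning daughter, its sister and
the mother centroid move toward the profile by their respective learning
rates. Growth stops when either ``max_cycles`` splits have happened (seven
cycles -> at most eight hard clusters) or every leaf's diversity is at or
below ``max_diversity``. Profiles here are 8-dimensional one-sided P-value
vectors, clustered raw (no re-standardization).

Hierarchical dendrograms over proteins or populations use plain agglomerative
clustering with Euclidean distance and average linkage (UPGMA) by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

__all__ = [
    "SOTACell",
    "SOTATree",
    "Dendrogram",
    "sota_cluster",
    "cell_diversity",
    "hierarchical_cluster",
]


@dataclass
class SOTACell:
    cell_id: int
    centroid: np.ndarray
    members: list[int] = field(default_factory=list)
    parent: int | None = None
    children: tuple[int, int] | None = None

    @property
    def is_leaf(self) -> bool:
        return self.children is None


@dataclass
class SOTATree:
    cells: list[SOTACell]
    labels: list[str]
    n_cycles: int

    def leaves(self) -> list[SOTACell]:
        return [c for c in self.cells if c.is_leaf]

    def assignments(self) -> pd.Series:
        """protein id -> cluster number (leaves numbered 1.. in cell order)."""
        lab = {}
        for k, cell in enumerate(self.leaves(), start=1):
            for m in cell.members:
                lab[self.labels[m]] = k
        return pd.Series(lab, name="cluster_id").loc[self.labels]

    def diversities(self, profiles: np.ndarray) -> list[float]:
        return [cell_diversity(profiles[c.members], c.centroid) for c in self.leaves()]


def cell_diversity(member_profiles: np.ndarray, centroid: np.ndarray) -> float:
    """Mean Euclidean distance of a cell's members to its centroid."""
    member_profiles = np.atleast_2d(np.asarray(member_profiles, float))
    if member_profiles.shape[0] == 0:
        raise ValueError("cell has no members")
    d = np.linalg.norm(member_profiles - np.asarray(centroid, float), axis=1)
    return float(d.mean())


def sota_cluster(
    profiles: pd.DataFrame | np.ndarray,
    max_cycles: int = 7,
    max_diversity: float = 0.8,
    rates: tuple[float, float, float] = (0.01, 0.005, 0.001),
    max_epochs: int = 1000,
    tol: float = 1e-6,
    seed: int | None = None,
) -> SOTATree:
    """Grow a SOTA tree over profile rows; leaves are the hard clusters.

    ``rates`` are the (winner, mother, sister) learning rates with
    winner >= mother >= sister > 0. Presentation order is the input row order,
    so the result is deterministic for a given input; ``seed`` is accepted for
    interface symmetry with the other stages but does not change the result.
    """
    if isinstance(profiles, pd.DataFrame):
        labels = [str(i) for i in profiles.index]
        X = profiles.to_numpy(float)
    else:
        X = np.asarray(profiles, float)
        labels = [str(i) for i in range(X.shape[0])]
    if X.ndim != 2 or X.shape[0] == 0:
        raise ValueError("profiles must be a non-empty 2-D array")
    if np.isnan(X).any():
        raise ValueError("profiles must be complete (no NaN)")
    w, m, s = rates
    if not (w >= m >= s > 0):
        raise ValueError("need winner >= mother >= sister > 0 learning rates")

    root = SOTACell(0, X.mean(axis=0).copy(), list(range(X.shape[0])))
    cells = [root]
    n_cycles = 0
    while n_cycles < max_cycles:
        leaves = [c for c in cells if c.is_leaf]
        div = [cell_diversity(X[c.members], c.centroid) if c.members else 0.0 for c in leaves]
        order = int(np.argmax(div))
        if div[order] <= max_diversity:
            break
        parent = leaves[order]
        members = parent.members
        if len(members) < 2:
            break
        # daughters: one at the parent centroid, one at the farthest member
        dists = np.linalg.norm(X[members] - parent.centroid, axis=1)
        far = members[int(np.argmax(dists))]
        d1 = SOTACell(len(cells), parent.centroid.copy(), parent=parent.cell_id)
        d2 = SOTACell(len(cells) + 1, X[far].copy(), parent=parent.cell_id)
        cells.extend([d1, d2])
        parent.children = (d1.cell_id, d2.cell_id)

        prev_err = np.inf
        for _ in range(max_epochs):
            err = 0.0
            for i in members:
                x = X[i]
                e1 = np.linalg.norm(x - d1.centroid)
                e2 = np.linalg.norm(x - d2.centroid)
                if e1 <= e2:
                    win, sib, err_i = d1, d2, e1
                else:
                    win, sib, err_i = d2, d1, e2
                win.centroid += w * (x - win.centroid)
                parent.centroid += m * (x - parent.centroid)
                sib.centroid += s * (x - sib.centroid)
                err += err_i
            if prev_err < np.inf and abs(prev_err - err) <= tol * max(prev_err, 1e-30):
                break
            prev_err = err
        # hard assignment to the nearer daughter
        for i in members:
            e1 = np.linalg.norm(X[i] - d1.centroid)
            e2 = np.linalg.norm(X[i] - d2.centroid)
            (d1 if e1 <= e2 else d2).members.append(i)
        parent.members = []
        # report centroids as the member means (empty daughter keeps adapted one)
        for d in (d1, d2):
            if d.members:
                d.centroid = X[d.members].mean(axis=0)
        n_cycles += 1
    return SOTATree(cells=cells, labels=labels, n_cycles=n_cycles)


@dataclass
class Dendrogram:
    linkage_matrix: np.ndarray
    labels: list[str]

    @property
    def heights(self) -> np.ndarray:
        return self.linkage_matrix[:, 2]

    def leaf_order(self) -> list[str]:
        return [self.labels[i] for i in hierarchy.leaves_list(self.linkage_matrix)]

    def to_newick(self) -> str:
        tree = hierarchy.to_tree(self.linkage_matrix)

        def rec(node, parent_dist) -> str:
            if node.is_leaf():
                return f"{self.labels[node.id]}:{parent_dist - node.dist:.6g}"
            left = rec(node.get_left(), node.dist)
            right = rec(node.get_right(), node.dist)
            return f"({left},{right}):{parent_dist - node.dist:.6g}"

        return rec(tree, tree.dist)[: -len(":0")] + ";"


def hierarchical_cluster(
    matrix: pd.DataFrame | np.ndarray,
    axis: str = "rows",
    linkage: str = "average",
) -> Dendrogram:
    """Euclidean agglomerative dendrogram over rows or columns."""
    if axis not in {"rows", "columns"}:
        raise ValueError("axis must be 'rows' or 'columns'")
    if isinstance(matrix, pd.DataFrame):
        data = matrix.to_numpy(float)
        labels = [str(x) for x in (matrix.index if axis == "rows" else matrix.columns)]
    else:
        data = np.asarray(matrix, float)
        n = data.shape[0 if axis == "rows" else 1]
        labels = [str(i) for i in range(n)]
    if axis == "columns":
        data = data.T
    if data.shape[0] < 2:
        raise ValueError("need at least 2 items to cluster")
    if np.isnan(data).any():
        raise ValueError("matrix must be complete (no NaN)")
    Z = hierarchy.linkage(pdist(data, metric="euclidean"), method=linkage)
    return Dendrogram(Z, labels)
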