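"""Tissue dendrogram from density non-overlap distances.

Two tissues are compared gene by gene: for each gene with a density estimate
in both tissues, the non-overlapping area 1 - integral(min(f1, f2)) of the two
unit-area curves is computed on the gene's shared grid, and the tissue
distance is the median over those genes.  Complete-linkage agglomerative
clustering of the distance matrix yields the tissue tree, exported as Newick
with branch lengths taken from the merge heights.
"""

from __future__ import annotations

import dataclasses
import itertools

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy
import scipy.spatial.distance

from .exceptions import AgepError, InputError
from .reference import ReferenceModel


def density_nonoverlap(
    d1: np.ndarray, d2: np.ndarray, grid: np.ndarray
) -> float:
    """1 minus the shared area of two unit-area densities on a common grid.

    0 for identical curves, 1 for disjoint supports; symmetric and clipped to
    [0, 1] against trapezoidal round-off.
    """
    d1 = np.asarray(d1, dtype=float)
    d2 = np.asarray(d2, dtype=float)
    if d1.shape != d2.shape or d1.shape != np.shape(grid):
        raise AgepError("densities must share one evaluation grid")
    overlap = float(np.trapezoid(np.minimum(d1, d2), grid))
    return float(np.clip(1.0 - overlap, 0.0, 1.0))


@dataclasses.dataclass
class TissueDistanceMatrix:
    distances: pd.DataFrame  # symmetric, zero diagonal, values in [0, 1]
    gene_counts: pd.DataFrame  # genes shared by each tissue pair


def tissue_distances(model: ReferenceModel) -> TissueDistanceMatrix:
    """Median per-gene density non-overlap between every pair of tissues."""
    tissues = model.tissues
    if len(tissues) < 2:
        raise InputError("need at least 2 tissues for a distance matrix")
    dist = pd.DataFrame(0.0, index=tissues, columns=tissues)
    counts = pd.DataFrame(0, index=tissues, columns=tissues)
    np.fill_diagonal(counts.values, 0)
    for t1, t2 in itertools.combinations(tissues, 2):
        vals = [
            density_nonoverlap(g.densities[t1], g.densities[t2], g.grid)
            for g in model.genes.values()
            if t1 in g.densities and t2 in g.densities
        ]
        if not vals:
            raise InputError(
                f"tissues {t1!r} and {t2!r} share no gene with densities; "
                "distance matrix cannot be completed"
            )
        dist.loc[t1, t2] = dist.loc[t2, t1] = float(np.median(vals))
        counts.loc[t1, t2] = counts.loc[t2, t1] = len(vals)
    return TissueDistanceMatrix(dist, counts)


@dataclasses.dataclass
class Dendrogram:
    labels: list[str]  # leaf labels in the order used for linkage
    linkage: np.ndarray  # scipy linkage matrix (n-1, 4)

    def newick(self) -> str:
        """Newick string with branch lengths from the merge heights."""
        root = scipy.cluster.hierarchy.to_tree(self.linkage)

        def render(node, parent_height: float) -> str:
            length = parent_height - node.dist
            if node.is_leaf():
                return f"{self.labels[node.id]}:{length:.6g}"
            left = render(node.left, node.dist)
            right = render(node.right, node.dist)
            return f"({left},{right}):{length:.6g}"

        left = render(root.left, root.dist)
        right = render(root.right, root.dist)
        return f"({left},{right});"

    def merge_heights(self) -> np.ndarray:
        return self.linkage[:, 2].copy()


def build_tree(distances: pd.DataFrame | TissueDistanceMatrix) -> Dendrogram:
    """Complete-linkage clustering of a tissue distance matrix.

    Labels are sorted lexicographically before clustering so equal-distance
    merges resolve deterministically.  Missing entries are rejected.
    """
    if isinstance(distances, TissueDistanceMatrix):
        distances = distances.distances
    if distances.isna().any().any():
        raise InputError("distance matrix contains missing entries")
    labels = sorted(distances.index)
    mat = distances.loc[labels, labels].to_numpy(dtype=float)
    if not np.allclose(mat, mat.T):
        raise InputError("distance matrix is not symmetric")
    condensed = scipy.spatial.distance.squareform(mat, checks=False)
    linkage = scipy.cluster.hierarchy.linkage(condensed, method="complete")
    return Dendrogram(labels=labels, linkage=linkage)
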