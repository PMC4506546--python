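"""Transcriptome-similarity analytics.

Samples are compared by Spearman-correlation distance D = 1 - SC over
genes, embedded with classical (Torgerson) multidimensional scaling and
clustered by complete linkage with optimal leaf ordering; gene rows are
z-scored for heatmap export.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform


def spearman_distance(norm: pd.DataFrame) -> pd.DataFrame:
    """Pairwise D = 1 - Spearman correlation between sample columns.

    Ties get average ranks. A constant column has no defined correlation
    and raises, naming the offending sample.
    """
    if norm.shape[1] < 2 or norm.shape[0] < 3:
        raise ValueError("need >= 2 samples and >= 3 genes")
    x = norm.to_numpy(dtype=float)
    const = x.std(axis=0) == 0
    if const.any():
        bad = norm.columns[const][0]
        raise ValueError(f"sample {bad!r} is constant; Spearman correlation undefined")
    ranks = np.apply_along_axis(sps.rankdata, 0, x)
    rho = np.corrcoef(ranks.T)
    d = 1.0 - rho
    np.fill_diagonal(d, 0.0)
    return pd.DataFrame(d, index=norm.columns, columns=norm.columns)


def classical_mds(d: pd.DataFrame, k: int = 2) -> pd.DataFrame:
    """Torgerson scaling: double-centre -D^2/2, eigendecompose, return the
    top-k coordinates scaled by sqrt(eigenvalue).

    Axes with non-positive eigenvalues are dropped with a warning (the
    distances then have no exact k-dimensional Euclidean representation).
    Sign convention: each axis is flipped so its largest-magnitude
    coordinate is positive.
    """
    n = d.shape[0]
    if k >= n:
        raise ValueError(f"k={k} must be smaller than the number of samples ({n})")
    dm = d.to_numpy(dtype=float)
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (dm**2) @ j
    eigval, eigvec = np.linalg.eigh(b)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    keep = min(k, int((eigval > 1e-10).sum()))
    if keep < k:
        warnings.warn(f"only {keep} positive eigenvalues; dropping {k - keep} axes")
    coords = eigvec[:, :keep] * np.sqrt(eigval[:keep])
    for axis in range(coords.shape[1]):
        col = coords[:, axis]
        if col[np.argmax(np.abs(col))] < 0:
            coords[:, axis] = -col
    return pd.DataFrame(coords, index=d.index, columns=[f"dim{i + 1}" for i in range(keep)])


def hier_cluster(d: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    """Complete-linkage clustering with optimal leaf ordering.

    Returns the scipy linkage matrix and the leaf order (sample ids) that
    minimizes the sum of adjacent-leaf distances over all subtree flips.
    """
    dm = d.to_numpy(dtype=float)
    condensed = squareform(dm, checks=False)
    link = hierarchy.linkage(condensed, method="complete")
    link = hierarchy.optimal_leaf_ordering(link, condensed)
    order = hierarchy.leaves_list(link)
    return link, [d.index[i] for i in order]


def dendrogram_to_newick(link: np.ndarray, labels: list[str]) -> str:
    """Newick export with branch lengths = parent height - child height."""
    tree = hierarchy.to_tree(link)

    def walk(node, parent_height):
        length = parent_height - node.dist
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.6g}"
        left = walk(node.left, node.dist)
        right = walk(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    left = walk(tree.left, tree.dist)
    right = walk(tree.right, tree.dist)
    return f"({left},{right});"


def standardize_rows(matrix: pd.DataFrame) -> pd.DataFrame:
    """Z-score each row to mean 0, SD 1 (population SD).

    Constant rows cannot be scaled; they are emitted as zeros with a
    warning.
    """
    x = matrix.to_numpy(dtype=float)
    mean = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    const = sd[:, 0] == 0
    if const.any():
        warnings.warn(f"{int(const.sum())} constant rows standardized to zeros")
    sd = np.where(sd == 0, 1.0, sd)
    z = (x - mean) / sd
    z[const] = 0.0
    return pd.DataFrame(z, index=matrix.index, columns=matrix.columns)
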