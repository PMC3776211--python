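"""Hierarchical clustering and red/green heat-map export.

Follows the Cluster/TreeView conventions of the microarray era: complete
linkage agglomeration on centred-Pearson-correlation distance, genes and
arrays clustered separately, and a red-black-green heat map of per-gene
median-centred log ratios saturated at +/-3.0 (0 -> black).  Euclidean
distance is available by flag.  A constant row has no defined correlation;
its distance to everything is set to the maximum (1.0) and flagged.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import dendrogram, linkage
from scipy.spatial.distance import pdist, squareform

__all__ = ["hierarchical_cluster", "ClusterHeatmap", "build_heatmap",
           "export_heatmap", "heatmap_rgb", "SATURATION"]

#: Log-ratio magnitude at which the colour scale saturates.
SATURATION = 3.0


@dataclass
class ClusterTree:
    order: list                 # leaf labels in dendrogram order
    linkage_matrix: np.ndarray  # scipy linkage encoding
    labels: list
    constant_items: list        # items with undefined correlation (flagged)


def _correlation_distance(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Centred-correlation condensed distance; constant rows -> distance 1."""
    sd = X.std(axis=1)
    constant = sd == 0
    dist = squareform(pdist(X, metric="correlation"), checks=False)
    if constant.any():
        dist[constant, :] = 1.0
        dist[:, constant] = 1.0
    np.fill_diagonal(dist, 0.0)
    return squareform(dist, checks=False), constant


def hierarchical_cluster(matrix: pd.DataFrame, axis: str = "genes", *,
                         metric: str = "correlation") -> ClusterTree:
    """Complete-linkage clustering of rows (``axis='genes'``) or columns.

    Ties are broken deterministically by input order (scipy's stable
    agglomeration); leaf order is scipy's standard subtree ordering.
    """
    if axis == "genes":
        X = matrix.to_numpy(dtype=float)
        labels = list(matrix.index)
    elif axis == "arrays":
        X = matrix.to_numpy(dtype=float).T
        labels = list(matrix.columns)
    else:
        raise ValueError("axis must be 'genes' or 'arrays'")
    if X.shape[0] < 2:
        raise ValueError("need >= 2 items to cluster")
    if metric == "correlation":
        condensed, constant = _correlation_distance(X)
    elif metric == "euclidean":
        condensed = pdist(X, metric="euclidean")
        constant = np.zeros(X.shape[0], dtype=bool)
    else:
        raise ValueError(f"unknown metric {metric!r}")
    Z = linkage(condensed, method="complete")
    leaf_order = dendrogram(Z, no_plot=True)["leaves"]
    return ClusterTree(order=[labels[i] for i in leaf_order],
                       linkage_matrix=Z, labels=labels,
                       constant_items=[labels[i] for i in np.where(constant)[0]])


@dataclass
class ClusterHeatmap:
    """Gene/array orders, linkage trees and the centred log-ratio matrix."""

    matrix: pd.DataFrame        # median-centred log ratios, reordered
    gene_tree: ClusterTree
    array_tree: ClusterTree
    saturation: float = SATURATION


def build_heatmap(matrix: pd.DataFrame, *, metric: str = "correlation",
                  center: bool = True) -> ClusterHeatmap:
    """Median-centre, cluster both axes, and return the ordered heat map."""
    from .sam import median_center
    M = median_center(matrix) if center else matrix.copy()
    gene_tree = hierarchical_cluster(M, "genes", metric=metric)
    array_tree = hierarchical_cluster(M, "arrays", metric=metric)
    ordered = M.loc[gene_tree.order, array_tree.order]
    return ClusterHeatmap(matrix=ordered, gene_tree=gene_tree,
                          array_tree=array_tree)


def heatmap_rgb(values, saturation: float = SATURATION) -> np.ndarray:
    """Map log ratios to the red-black-green scale.

    0 -> black; positive -> red ramp saturating at ``+saturation``;
    negative -> green ramp saturating at ``-saturation`` and below.
    """
    v = np.clip(np.asarray(values, dtype=float) / saturation, -1.0, 1.0)
    rgb = np.zeros(v.shape + (3,))
    rgb[..., 0] = np.where(v > 0, v, 0.0)    # red channel
    rgb[..., 1] = np.where(v < 0, -v, 0.0)   # green channel
    return rgb


def export_heatmap(heatmap: ClusterHeatmap, png_path=None, tsv_path=None
                   ) -> pd.DataFrame:
    """Write the heat-map image and/or the ordered numeric TSV.

    The TSV carries the exact reordered matrix so the figure is testable;
    returns that frame.
    """
    ordered = heatmap.matrix
    if tsv_path is not None:
        ordered.to_csv(tsv_path, sep="\t", index_label="gene")
    if png_path is not None:
        import matplotlib
        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt
        rgb = heatmap_rgb(ordered.to_numpy(), heatmap.saturation)
        h = max(2.0, 0.12 * ordered.shape[0])
        w = max(3.0, 0.25 * ordered.shape[1])
        fig, ax = plt.subplots(figsize=(w, min(h, 40)))
        ax.imshow(rgb, aspect="auto", interpolation="nearest")
        ax.set_xticks(range(ordered.shape[1]))
        ax.set_xticklabels(ordered.columns, rotation=90, fontsize=5)
        ax.set_yticks(range(ordered.shape[0]))
        ax.set_yticklabels(ordered.index, fontsize=4)
        fig.tight_layout()
        fig.savefig(png_path, dpi=150)
        plt.close(fig)
    return ordered
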