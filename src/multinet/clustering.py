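"""Ward clustering of the 3D embedding.

Clusters are built by Ward's minimum-variance agglomeration on the
Euclidean distances between 3D coordinates (scipy's Lance-Williams
implementation).  Heights follow the convention in which two singletons
merge at their Euclidean distance, i.e. the reported height is the square
root of twice the within-cluster variance increase; a squared-height
convention is selectable.  Cutting the tree at a dissimilarity threshold
(or into k clusters) yields mutually exclusive, exhaustive clusters, which
are then summarized by size, mean maximum multiplicity and — when a causal
gene list is supplied — causal-gene counts plus the Spearman rank
correlation between cluster means and counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform
from sklearn.base import BaseEstimator, ClusterMixin

from .layout import Embedding3D

__all__ = [
    "ClusterTree",
    "ClusterAssignment",
    "WardClustering",
    "euclidean_distances",
    "ward_cluster",
    "cut_tree",
    "cluster_summary",
    "to_newick",
    "write_merge_table",
]


def euclidean_distances(emb: Embedding3D) -> np.ndarray:
    """Symmetric Euclidean distance matrix between 3D coordinates."""
    return squareform(pdist(emb.coords))


@dataclass(frozen=True)
class ClusterTree:
    """Ward merge history in scipy linkage form.

    ``linkage`` rows are ``(left, right, height, size)``; heights are
    non-decreasing (Ward monotonicity, asserted) and sizes conserve.
    """

    leaves: tuple[str, ...]
    linkage: np.ndarray
    squared: bool = False

    def __post_init__(self) -> None:
        z = self.linkage
        if z.shape != (len(self.leaves) - 1, 4):
            raise ValueError("linkage shape does not match leaf count")
        h = z[:, 2]
        if np.any(np.diff(h) < -1e-9):
            raise ValueError("Ward heights must be non-decreasing")
        if int(z[-1, 3]) != len(self.leaves):
            raise ValueError("root size must equal leaf count")

    @property
    def heights(self) -> np.ndarray:
        return self.linkage[:, 2]


@dataclass
class ClusterAssignment:
    """A cut of the tree: one cluster id per leaf (mutually exclusive)."""

    cut_height: float | None
    labels: pd.Series  # leaf -> cluster id (1-based)
    summary: pd.DataFrame | None = None
    spearman: tuple[float, float, float] | None = None  # (rs, t, p)

    @property
    def n_clusters(self) -> int:
        return int(self.labels.nunique())


class WardClustering(BaseEstimator, ClusterMixin):
    """Ward agglomeration over feature vectors or precomputed distances.

    Parameters
    ----------
    n_clusters : int or None
        Cut into this many clusters.
    distance_threshold : float or None
        Cut at this dissimilarity instead (clusters are the connected leaf
        sets whose merges lie at or below the threshold).
    metric : {"euclidean", "precomputed"}
    squared : bool
        Report squared heights (Ward cost) instead of their square roots.

    Attributes
    ----------
    tree_ : ClusterTree
    labels_ : ndarray of cluster ids (only when a cut is requested)
    """

    def __init__(
        self,
        n_clusters: int | None = None,
        distance_threshold: float | None = None,
        metric: str = "euclidean",
        squared: bool = False,
    ):
        self.n_clusters = n_clusters
        self.distance_threshold = distance_threshold
        self.metric = metric
        self.squared = squared

    def fit(self, X: np.ndarray, y=None, leaves: Iterable[str] | None = None):
        X = np.asarray(X, dtype=float)
        if self.metric == "precomputed":
            if X.ndim != 2 or X.shape[0] != X.shape[1]:
                raise ValueError("precomputed X must be square")
            if not np.allclose(X, X.T, atol=1e-8):
                raise ValueError("precomputed distance matrix must be symmetric")
            condensed = squareform(X, checks=False)
            n = X.shape[0]
        elif self.metric == "euclidean":
            condensed = pdist(X)
            n = X.shape[0]
        else:
            raise ValueError("metric must be 'euclidean' or 'precomputed'")
        if n < 2:
            raise ValueError("need at least 2 leaves")
        z = hierarchy.linkage(condensed, method="ward")
        if self.squared:
            z = z.copy()
            z[:, 2] = z[:, 2] ** 2
        names = tuple(leaves) if leaves is not None else tuple(str(i) for i in range(n))
        self.tree_ = ClusterTree(leaves=names, linkage=z, squared=self.squared)
        if self.n_clusters is not None:
            self.labels_ = hierarchy.fcluster(z, t=self.n_clusters, criterion="maxclust")
        elif self.distance_threshold is not None:
            self.labels_ = hierarchy.fcluster(z, t=self.distance_threshold, criterion="distance")
        return self


def ward_cluster(distances: np.ndarray, leaves: Iterable[str] | None = None,
                 squared: bool = False) -> ClusterTree:
    """Ward merge tree from a symmetric distance matrix."""
    est = WardClustering(metric="precomputed", squared=squared)
    est.fit(np.asarray(distances, dtype=float), leaves=leaves)
    return est.tree_


def cut_tree(
    tree: ClusterTree,
    threshold: float | None = None,
    k: int | None = None,
) -> ClusterAssignment:
    """Cut the tree at a dissimilarity ``threshold`` or into ``k`` clusters.

    Threshold cuts keep together every leaf pair whose merge height is at
    or below the threshold; ids are renumbered 1..n_clusters in leaf order.
    """
    if (threshold is None) == (k is None):
        raise ValueError("provide exactly one of threshold or k")
    if threshold is not None:
        if threshold < 0:
            raise ValueError("threshold must be >= 0")
        raw = hierarchy.fcluster(tree.linkage, t=threshold, criterion="distance")
    else:
        raw = hierarchy.fcluster(tree.linkage, t=k, criterion="maxclust")
    # renumber cluster ids deterministically by first appearance in leaf order
    remap: dict[int, int] = {}
    labels = []
    for c in raw:
        if c not in remap:
            remap[c] = len(remap) + 1
        labels.append(remap[c])
    series = pd.Series(labels, index=list(tree.leaves), name="cluster")
    return ClusterAssignment(cut_height=threshold, labels=series)


def cluster_summary(
    assign: ClusterAssignment,
    node_values: Mapping[str, float] | pd.Series,
    causal: set[str] | frozenset[str] | None = None,
) -> ClusterAssignment:
    """Fill per-cluster size, mean value and causal counts on ``assign``.

    ``node_values`` is typically the per-node maximum multiplicity.  With a
    non-empty causal set the Spearman rank correlation between cluster
    means and causal counts is computed (reported as None when ranks are
    degenerate, e.g. identical means).
    """
    from .evaluation import spearman_rank

    values = pd.Series(dict(node_values), dtype=float)
    missing = set(assign.labels.index) - set(values.index)
    if missing:
        raise ValueError(f"node_values missing {sorted(missing)[:3]}...")
    causal = causal or frozenset()
    rows = []
    for cid, members in assign.labels.groupby(assign.labels).groups.items():
        members = list(members)
        rows.append(
            {
                "cluster": cid,
                "size": len(members),
                "mean_max_multiplicity": float(values.loc[members].mean()),
                "n_causal": sum(1 for m in members if m in causal),
            }
        )
    summary = pd.DataFrame(rows).set_index("cluster").sort_index()
    assign.summary = summary
    assign.spearman = None
    if causal and len(summary) >= 3:
        means = summary["mean_max_multiplicity"].values
        counts = summary["n_causal"].values
        if len(np.unique(means)) > 1 and len(np.unique(counts)) > 1:
            assign.spearman = spearman_rank(means, counts)
    return assign


def _build_newick(node, leaves, parent_height: float) -> str:
    if node.is_leaf():
        return f"{leaves[node.id]}:{parent_height - 0.0:g}"
    left = _build_newick(node.left, leaves, node.dist)
    right = _build_newick(node.right, leaves, node.dist)
    return f"({left},{right}):{parent_height - node.dist:g}"


def to_newick(tree: ClusterTree) -> str:
    """Newick serialization with merge heights as cumulative node depths."""
    root = hierarchy.to_tree(tree.linkage)
    left = _build_newick(root.left, tree.leaves, root.dist)
    right = _build_newick(root.right, tree.leaves, root.dist)
    return f"({left},{right});"


def write_merge_table(tree: ClusterTree, path: str | Path) -> None:
    z = tree.linkage
    frame = pd.DataFrame(
        {
            "left": z[:, 0].astype(int),
            "right": z[:, 1].astype(int),
            "height": z[:, 2],
            "size": z[:, 3].astype(int),
        }
    )
    frame.to_csv(path, sep="\t", index=False)
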