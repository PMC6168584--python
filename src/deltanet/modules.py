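"""Biomarker community detection on the correlation-derived distance.

The dissimilarity between two biomarkers is ``1 - |rho|``, so strongly
correlated changes (of either sign) are close.  Biomarkers are clustered
agglomeratively and the dendrogram is decomposed adaptively: correlation
dendrograms rarely offer a single clean cut height, so instead of one static
cut the tree is cut just below its top merges, branches whose internal merge
heights show a clear gap are split recursively, and clusters smaller than a
minimum size are dissolved into their nearest neighbour cluster (or left
unassigned, label 0).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import ClusterNode, linkage as scipy_linkage, to_tree
from scipy.spatial.distance import squareform

__all__ = [
    "distance_from_correlations",
    "Dendrogram",
    "hierarchical_cluster",
    "ClusterAssignment",
    "dynamic_tree_cut",
    "write_assignment",
]


def distance_from_correlations(entries: pd.DataFrame) -> pd.DataFrame:
    """Square distance matrix d = 1 - |rho| over all biomarkers in ``entries``.

    Pairs absent from the table (untestable) are imputed with rho = 0, i.e.
    maximal distance 1, with a warning; the diagonal is 0.
    """
    nodes = sorted(set(entries["biomarker_a"]) | set(entries["biomarker_b"]))
    d = pd.DataFrame(1.0, index=nodes, columns=nodes)
    np.fill_diagonal(d.values, 0.0)
    seen = set()
    for row in entries.itertuples(index=False):
        dist = 1.0 - abs(row.rho)
        d.loc[row.biomarker_a, row.biomarker_b] = dist
        d.loc[row.biomarker_b, row.biomarker_a] = dist
        seen.add(frozenset((row.biomarker_a, row.biomarker_b)))
    n_missing = len(nodes) * (len(nodes) - 1) // 2 - len(seen)
    if n_missing:
        warnings.warn(
            f"{n_missing} untestable biomarker pair(s) imputed with rho=0 "
            "(distance 1) for clustering",
            stacklevel=2,
        )
    return d


@dataclass
class Dendrogram:
    """Agglomeration result: scipy linkage matrix plus leaf labels."""

    merges: np.ndarray  # (n-1, 4) scipy linkage matrix
    labels: list[str]

    @property
    def heights(self) -> np.ndarray:
        return self.merges[:, 2]


def _validate_distance(d: pd.DataFrame) -> np.ndarray:
    arr = np.asarray(d, dtype=float)
    if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(arr, arr.T, atol=1e-12):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(arr), 0.0):
        raise ValueError("distance matrix must have a zero diagonal")
    if arr.min() < 0:
        raise ValueError("distances must be nonnegative")
    return arr


def hierarchical_cluster(d: pd.DataFrame, linkage: str = "average") -> Dendrogram:
    """Agglomerative clustering of a validated distance matrix.

    ``linkage`` is one of average (default), complete, single.  The
    agglomeration itself is scipy's, which is deterministic for a given
    input (ties resolved by its internal ordering).
    """
    if linkage not in ("average", "complete", "single"):
        raise ValueError(f"unsupported linkage: {linkage!r}")
    arr = _validate_distance(d)
    if arr.shape[0] < 2:
        raise ValueError("need at least 2 leaves")
    labels = [str(c) for c in d.columns] if isinstance(d, pd.DataFrame) else [
        str(i) for i in range(arr.shape[0])
    ]
    merges = scipy_linkage(squareform(arr, checks=False), method=linkage)
    return Dendrogram(merges=merges, labels=labels)


@dataclass
class ClusterAssignment:
    """Map biomarker -> cluster label; 0 means unassigned."""

    labels: dict[str, int]
    parameters: dict

    def as_series(self) -> pd.Series:
        return pd.Series(self.labels, name="cluster_label").sort_index()

    @property
    def n_clusters(self) -> int:
        return len({v for v in self.labels.values() if v != 0})


def _subtree_heights(node: ClusterNode, out: list[float]) -> None:
    if node.is_leaf():
        return
    out.append(node.dist)
    _subtree_heights(node.left, out)
    _subtree_heights(node.right, out)


def _leaves(node: ClusterNode) -> list[int]:
    return node.pre_order(lambda leaf: leaf.id)


def _split_branch(
    node: ClusterNode, gap_fraction: float
) -> list[tuple[list[int], float]]:
    """Recursively split a below-threshold branch at pronounced height gaps.

    A branch shows distinct sub-branches when its root merge sits well above
    everything inside it: the branch is split when the gap between the root
    merge height and the highest merge inside either child exceeds
    ``gap_fraction`` of the root height.  Otherwise the branch is one
    candidate cluster.  Returns (leaf ids, top merge height) per candidate.
    """
    if node.is_leaf():
        return [([node.id], 0.0)]
    child_max = max(
        (h for child in (node.left, node.right) for h in _child_heights(child)),
        default=None,
    )
    if child_max is not None and node.dist > 0:
        gap = node.dist - child_max
        if gap > gap_fraction * node.dist:
            return _split_branch(node.left, gap_fraction) + _split_branch(
                node.right, gap_fraction
            )
    return [(_leaves(node), node.dist)]


def _child_heights(child: ClusterNode) -> list[float]:
    out: list[float] = []
    _subtree_heights(child, out)
    return out


def dynamic_tree_cut(
    dend: Dendrogram,
    d: pd.DataFrame,
    min_cluster_size: int = 3,
    cut_height_fraction: float = 0.99,
    split_gap_fraction: float = 0.5,
) -> ClusterAssignment:
    """Adaptive decomposition of the dendrogram into biomarker communities.

    1. A static cut removes merges whose height exceeds
       ``h_min + cut_height_fraction * (h_max - h_min)`` (the top of the
       merge-height range); the surviving subtrees are candidate branches.
       A degenerate tree (all merges at one height) is kept whole.
    2. Each candidate branch is recursively split where its internal height
       profile shows a pronounced gap (see ``split_gap_fraction``).
    3. Candidates smaller than ``min_cluster_size`` are dissolved: each
       member joins the nearest retained cluster by average distance if that
       distance is within the cluster's top merge height, else gets label 0.

    Labels are arbitrary positive integers (compare partitions up to
    relabeling); parameters are recorded on the result.
    """
    if min_cluster_size < 1:
        raise ValueError("min_cluster_size must be >= 1")
    arr = _validate_distance(d)
    labels = list(dend.labels)
    if isinstance(d, pd.DataFrame):
        if sorted(labels) != sorted(str(c) for c in d.columns):
            raise ValueError("dendrogram and distance matrix leaves differ")
        arr = np.asarray(d.loc[labels, labels], dtype=float)

    heights = dend.heights
    h_min, h_max = float(heights.min()), float(heights.max())
    threshold = h_min + cut_height_fraction * (h_max - h_min)

    root = to_tree(dend.merges)
    branches: list[ClusterNode] = []

    def collect(node: ClusterNode) -> None:
        if (not node.is_leaf()) and node.dist > threshold:
            collect(node.left)
            collect(node.right)
        else:
            branches.append(node)

    collect(root)
    candidates: list[tuple[list[int], float]] = []
    for branch in branches:
        candidates.extend(_split_branch(branch, split_gap_fraction))

    retained = [c for c in candidates if len(c[0]) >= min_cluster_size]
    dissolved = [c for c in candidates if len(c[0]) < min_cluster_size]

    assignment = {name: 0 for name in labels}
    for k, (members, _height) in enumerate(retained, start=1):
        for idx in members:
            assignment[labels[idx]] = k

    for members, _height in dissolved:
        for idx in members:
            best_k, best_dist = 0, np.inf
            for k, (cluster_members, top_height) in enumerate(retained, start=1):
                avg = float(np.mean([arr[idx, j] for j in cluster_members]))
                if avg < best_dist:
                    best_k, best_dist = k, avg
            if retained and best_dist <= retained[best_k - 1][1]:
                assignment[labels[idx]] = best_k

    return ClusterAssignment(
        labels=assignment,
        parameters={
            "linkage_heights": [h_min, h_max],
            "min_cluster_size": min_cluster_size,
            "cut_height_fraction": cut_height_fraction,
            "split_gap_fraction": split_gap_fraction,
        },
    )


def write_assignment(assignment: ClusterAssignment, path) -> None:
    """Cluster assignment CSV: biomarker,cluster_label (0 = unassigned)."""
    assignment.as_series().rename_axis("biomarker").to_csv(path)
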