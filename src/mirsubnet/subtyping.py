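"""Hierarchical subtyping on correlation distances.

Discovery configuration: centered Pearson distance + average linkage.
Validation configuration: Pearson distance + ward linkage (the ward-on-
dissimilarity contract, i.e. scipy's ward applied to the given distances,
equivalent to the hclust ward.D2 treatment of a dissimilarity object).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.cluster.hierarchy import cut_tree, linkage as scipy_linkage
from scipy.spatial.distance import squareform

from mirsubnet.io_core import ExpressionMatrix, get_logger

log = get_logger("subtyping")

_LINKAGES = {"average", "ward"}
_DISTANCES = {"centered_pearson", "pearson"}


def pearson_distance(m: ExpressionMatrix, centered: bool = True) -> np.ndarray:
    """Correlation distance between sample profiles: d = 1 - r.

    ``centered`` subtracts each profile's mean (ordinary Pearson r over
    features); uncentered correlates about zero (cosine similarity).
    """
    if not m.detected.all():
        raise ValueError("undetected cells present — preprocess first")
    if m.n_features < 3:
        raise ValueError("need at least 3 features per profile")
    x = m.values.astype(float)  # features x samples
    if centered:
        x = x - x.mean(axis=0, keepdims=True)
        norms = np.linalg.norm(x, axis=0)
        for j in np.flatnonzero(norms == 0):
            raise ValueError(f"zero-variance profile for sample {m.sample_ids[j]!r}")
    else:
        norms = np.linalg.norm(x, axis=0)
        for j in np.flatnonzero(norms == 0):
            raise ValueError(f"all-zero profile for sample {m.sample_ids[j]!r}")
    r = (x / norms).T @ (x / norms)
    r = np.clip(r, -1.0, 1.0)
    d = 1.0 - r
    np.fill_diagonal(d, 0.0)
    return (d + d.T) / 2.0


@dataclass
class Dendrogram:
    """Agglomerative merge tree (scipy linkage encoding) with provenance."""

    merges: np.ndarray  # scipy linkage matrix, (n-1) x 4
    leaf_ids: list[str]
    linkage: str
    distance: str

    def __post_init__(self) -> None:
        self.merges = np.asarray(self.merges, dtype=float)
        n = len(self.leaf_ids)
        if self.merges.shape != (n - 1, 4):
            raise ValueError("expected n-1 merges for n leaves")
        if self.linkage not in _LINKAGES:
            raise ValueError(f"unknown linkage {self.linkage!r}")
        if self.distance not in _DISTANCES:
            raise ValueError(f"unknown distance {self.distance!r}")

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_ids)

    def _children(self) -> dict[int, tuple[int, int]]:
        n = self.n_leaves
        return {n + i: (int(a), int(b))
                for i, (a, b, _, _) in enumerate(self.merges[:, :4])}

    def _height(self, node: int) -> float:
        n = self.n_leaves
        return 0.0 if node < n else float(self.merges[node - n, 2])

    def leaf_order(self) -> list[int]:
        """Leaf indices with the tighter (lower) subtree on the left.

        Ties break by the smallest leaf index in the subtree, making the
        order deterministic.
        """
        children = self._children()
        n = self.n_leaves
        min_leaf: dict[int, int] = {}

        def _min_leaf(node: int) -> int:
            if node in min_leaf:
                return min_leaf[node]
            if node < n:
                min_leaf[node] = node
            else:
                a, b = children[node]
                min_leaf[node] = min(_min_leaf(a), _min_leaf(b))
            return min_leaf[node]

        order: list[int] = []
        stack = [2 * n - 2]
        while stack:
            node = stack.pop()
            if node < n:
                order.append(node)
                continue
            a, b = children[node]
            ka = (self._height(a), _min_leaf(a))
            kb = (self._height(b), _min_leaf(b))
            left, right = (a, b) if ka <= kb else (b, a)
            stack.append(right)
            stack.append(left)
        return order

    def to_newick(self) -> str:
        """Newick string with branch lengths from merge heights."""
        children = self._children()
        n = self.n_leaves

        def render(node: int, parent_h: float) -> str:
            bl = parent_h - self._height(node)
            if node < n:
                return f"{self.leaf_ids[node]}:{bl:.6g}"
            a, b = children[node]
            h = self._height(node)
            return f"({render(a, h)},{render(b, h)}):{bl:.6g}"

        root = 2 * n - 2
        h = self._height(root)
        a, b = children[root]
        return f"({render(a, h)},{render(b, h)});"


@dataclass
class SubtypeAssignment:
    labels: dict[str, str]  # sample -> label
    k: int
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        groups = set(self.labels.values())
        if len(groups) != self.k:
            raise ValueError(f"expected exactly {self.k} nonempty groups, got {len(groups)}")

    def group(self, label: str) -> list[str]:
        return [s for s, l in self.labels.items() if l == label]

    def label_vector(self, sample_ids: Sequence[str]) -> list[str]:
        return [self.labels[s] for s in sample_ids]


def cluster_samples(d: np.ndarray, leaf_ids: Sequence[str], linkage: str = "average",
                    distance: str = "centered_pearson") -> Dendrogram:
    """Agglomerative clustering of a precomputed distance matrix."""
    d = np.asarray(d, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if d.shape[0] != len(leaf_ids):
        raise ValueError("leaf ids do not match distance matrix")
    if d.shape[0] < 2:
        raise ValueError("need at least 2 items to cluster")
    if not np.allclose(d, d.T, atol=1e-10):
        raise ValueError("distance matrix must be symmetric")
    if linkage not in _LINKAGES:
        raise ValueError(f"unknown linkage {linkage!r}")
    condensed = squareform(d, checks=False)
    merges = scipy_linkage(condensed, method=linkage)
    return Dendrogram(merges, list(leaf_ids), linkage, distance)


def cut_k(dend: Dendrogram, k: int) -> SubtypeAssignment:
    """Flat clusters from removing the k-1 highest merges.

    Labels S1..Sk are assigned in order of first-occurring sample.  Ties at
    the cut height resolve by merge index order (logged).
    """
    n = dend.n_leaves
    if not (1 <= k <= n):
        raise ValueError(f"k must be in [1, {n}]")
    heights = dend.merges[:, 2]
    if k > 1 and k < n and heights[-(k - 1)] == heights[-k]:
        log.info("cut_k: tied merge heights at the cut — resolved by merge index order")
    raw = cut_tree(dend.merges, n_clusters=k).ravel()
    relabel: dict[int, str] = {}
    labels: dict[str, str] = {}
    for leaf, c in zip(dend.leaf_ids, raw):
        if c not in relabel:
            relabel[c] = f"S{len(relabel) + 1}"
        labels[leaf] = relabel[c]
    return SubtypeAssignment(
        labels=labels, k=k,
        provenance={"linkage": dend.linkage, "distance": dend.distance, "k": k},
    )


def subtype_cohort(m: ExpressionMatrix, k: int = 3, linkage: str = "average",
                   centered: bool = True) -> tuple[SubtypeAssignment, Dendrogram]:
    """Distance -> dendrogram -> k-cut in one call (sample axis)."""
    distance = "centered_pearson" if centered else "pearson"
    d = pearson_distance(m, centered=centered)
    dend = cluster_samples(d, m.sample_ids, linkage=linkage, distance=distance)
    return cut_k(dend, k), dend


def order_features(m: ExpressionMatrix, linkage: str = "average",
                   centered: bool = True) -> tuple[list[str], Dendrogram]:
    """Feature ordering by clustering the transposed matrix (heatmap rows)."""
    transposed = ExpressionMatrix(
        list(m.sample_ids), list(m.feature_ids),
        m.values.T.copy(), m.detected.T.copy(), m.scale_tag,
    )
    d = pearson_distance(transposed, centered=centered)
    dend = cluster_samples(
        d, m.feature_ids, linkage=linkage,
        distance="centered_pearson" if centered else "pearson",
    )
    return [m.feature_ids[i] for i in dend.leaf_order()], dend
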