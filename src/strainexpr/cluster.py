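"""Fold-change heat-map tiers and Ward minimum-variance strain clustering.

Expression differences are taken against a reference strain on the least-
square-mean (residual) scale; each gene's differences are z-scaled and
binned into a seven-tier categorical scale for heat-map display.  Strains
are clustered by Ward's minimum-variance criterion: at each step, merge the
pair of clusters whose fusion least increases the total within-cluster sum
of squares (Euclidean geometry),

    d(A, B) = |A||B| / (|A| + |B|) * ||centroid(A) - centroid(B)||^2 ,

with merge heights recorded as these objective increments.  Node support is
estimated by resampling genes (columns) with replacement, reclustering, and
counting how often each original leaf bipartition recurs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "FoldChangeMatrix",
    "DendroNode",
    "Dendrogram",
    "fold_change",
    "ward_cluster",
    "bootstrap_support",
    "classify_clusters",
    "standardize_genes",
]

DEFAULT_TIER_EDGES = (-2.5, -1.5, -0.5, 0.5, 1.5, 2.5)


@dataclass
class FoldChangeMatrix:
    """Signed expression differences vs a reference strain, plus tier labels."""

    values: pd.DataFrame   # strains × genes, reference row ≡ 0
    tiers: pd.DataFrame    # same shape, integer labels 1..7 (4 = no change)
    reference: str
    edges: tuple[float, ...] = DEFAULT_TIER_EDGES


def fold_change(
    means, reference: str, edges: tuple[float, ...] = DEFAULT_TIER_EDGES
) -> FoldChangeMatrix:
    """Per-gene differences against ``reference`` with seven-tier labels.

    Tiers bin the per-gene z-scaled difference at symmetric edges (default
    ±0.5, ±1.5, ±2.5); a value exactly on an edge goes to the lower tier.
    """
    values = means.values if hasattr(means, "values") and isinstance(
        getattr(means, "values"), pd.DataFrame) else pd.DataFrame(means)
    if reference not in values.index:
        raise ValueError(f"reference strain {reference!r} not present")
    diff = values - values.loc[reference]
    sd = diff.std(axis=0, ddof=1).replace(0.0, np.nan)
    z = diff.div(sd, axis=1).fillna(0.0)
    edges_arr = np.asarray(edges, dtype=float)
    tiers = pd.DataFrame(
        np.digitize(z.to_numpy(), edges_arr, right=True) + 1,
        index=diff.index, columns=diff.columns,
    )
    return FoldChangeMatrix(diff, tiers, reference, tuple(edges))


@dataclass
class DendroNode:
    leaves: frozenset
    height: float = 0.0
    children: tuple["DendroNode", "DendroNode"] | None = None
    support: float | None = None

    @property
    def is_leaf(self) -> bool:
        return self.children is None

    @property
    def name(self) -> str:
        return min(self.leaves)


@dataclass
class Dendrogram:
    root: DendroNode
    leaf_names: tuple[str, ...]

    def internal_nodes(self) -> list[DendroNode]:
        out: list[DendroNode] = []

        def walk(node: DendroNode) -> None:
            if not node.is_leaf:
                out.append(node)
                for ch in node.children:
                    walk(ch)

        walk(self.root)
        return out

    def merge_heights(self) -> list[float]:
        return sorted(n.height for n in self.internal_nodes())

    def splits(self) -> set[frozenset]:
        """Canonical leaf bipartitions, one per internal node.

        A node's clade and its complement are the same (unordered) split; the
        canonical representative is the side containing the lexicographically
        smallest leaf of the whole tree.
        """
        all_leaves = frozenset(self.leaf_names)
        anchor = min(all_leaves)
        out = set()
        for node in self.internal_nodes():
            side = node.leaves if anchor in node.leaves else all_leaves - node.leaves
            out.add(frozenset(side))
        return out

    def cut(self, k: int) -> pd.Series:
        """Cut at ``k`` clusters; labels 0..k-1 by each cluster's smallest leaf."""
        n = len(self.leaf_names)
        if not 1 <= k <= n:
            raise ValueError(f"k must be in [1, {n}]")
        clusters = [self.root]
        while len(clusters) < k:
            # split the cluster with the highest merge (ties: smallest leaf name)
            cand = sorted(
                (c for c in clusters if not c.is_leaf),
                key=lambda c: (-c.height, c.name),
            )[0]
            clusters.remove(cand)
            clusters.extend(cand.children)
        clusters.sort(key=lambda c: c.name)
        labels = {}
        for i, c in enumerate(clusters):
            for leaf in c.leaves:
                labels[leaf] = i
        return pd.Series(labels, name="cluster").sort_index()

    def to_newick(self) -> str:
        """Newick string: support as internal labels, height gaps as lengths."""

        def fmt(node: DendroNode, parent_height: float) -> str:
            length = parent_height - node.height
            if node.is_leaf:
                return f"{node.name}:{length:.6g}"
            kids = sorted(node.children, key=lambda c: c.name)
            inner = ",".join(fmt(c, node.height) for c in kids)
            label = "" if node.support is None else f"{node.support:.3g}"
            return f"({inner}){label}:{length:.6g}"

        root = self.root
        if root.is_leaf:
            return f"{root.name};"
        kids = sorted(root.children, key=lambda c: c.name)
        inner = ",".join(fmt(c, root.height) for c in kids)
        label = "" if root.support is None else f"{root.support:.3g}"
        return f"({inner}){label};"


def ward_cluster(matrix: pd.DataFrame) -> Dendrogram:
    """Agglomerate strains by Ward's minimum-variance criterion.

    ``matrix`` is strains × genes with no missing cells (all-missing gene
    columns are dropped with a warning, any other missingness is an error).
    Ties in the merge objective are broken by the lexicographically smallest
    (strain-name) cluster pair, so the result is independent of input order.
    """
    matrix = pd.DataFrame(matrix)
    if matrix.index.has_duplicates:
        raise ValueError("duplicate strain names")
    if matrix.shape[0] < 2 or matrix.shape[1] < 1:
        raise ValueError("need >=2 strains and >=1 gene")
    all_missing = matrix.columns[matrix.isna().all()]
    if len(all_missing):
        import logging

        logging.getLogger(__name__).warning(
            "dropping %d all-missing gene columns", len(all_missing))
        matrix = matrix.drop(columns=all_missing)
    if matrix.isna().any().any():
        raise ValueError("missing cells in clustering input")

    nodes: list[DendroNode] = []
    centroids: list[np.ndarray] = []
    sizes: list[int] = []
    for name in matrix.index:
        nodes.append(DendroNode(frozenset([str(name)])))
        centroids.append(matrix.loc[name].to_numpy(dtype=float))
        sizes.append(1)

    while len(nodes) > 1:
        best = None
        for i in range(len(nodes)):
            for j in range(i + 1, len(nodes)):
                d = (
                    sizes[i] * sizes[j] / (sizes[i] + sizes[j])
                    * float(((centroids[i] - centroids[j]) ** 2).sum())
                )
                pair_key = tuple(sorted((nodes[i].name, nodes[j].name)))
                cand = (d, pair_key, i, j)
                if best is None or cand[:2] < best[:2]:
                    best = cand
        d, _, i, j = best
        merged = DendroNode(
            nodes[i].leaves | nodes[j].leaves,
            height=d,
            children=(nodes[i], nodes[j]),
        )
        new_centroid = (sizes[i] * centroids[i] + sizes[j] * centroids[j]) / (
            sizes[i] + sizes[j]
        )
        for idx in sorted((i, j), reverse=True):
            del nodes[idx], centroids[idx], sizes[idx]
        nodes.append(merged)
        centroids.append(new_centroid)
        sizes.append(len(merged.leaves))
    return Dendrogram(nodes[0], tuple(sorted(str(s) for s in matrix.index)))


def bootstrap_support(
    matrix: pd.DataFrame, B: int, seed: int
) -> Dendrogram:
    """Ward tree with per-node bootstrap support from gene resampling.

    ``B`` matrices are drawn by resampling gene columns with replacement
    (after a canonical column sort, so support is invariant to input column
    order), each is re-clustered, and every original internal node's support
    is the fraction of bootstrap trees containing the same leaf bipartition.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    matrix = pd.DataFrame(matrix)
    if matrix.shape[1] < 2:
        raise ValueError("bootstrap needs >=2 genes to resample")
    matrix = matrix[sorted(matrix.columns)]
    tree = ward_cluster(matrix)
    rng = np.random.default_rng(seed)
    counts: dict[frozenset, int] = {}
    arr = matrix.to_numpy(dtype=float)
    n_genes = arr.shape[1]
    for _ in range(B):
        idx = rng.integers(0, n_genes, size=n_genes)
        boot = pd.DataFrame(arr[:, idx], index=matrix.index)
        for split in ward_cluster(boot).splits():
            counts[split] = counts.get(split, 0) + 1
    all_leaves = frozenset(tree.leaf_names)
    anchor = min(all_leaves)
    for node in tree.internal_nodes():
        if node.leaves == all_leaves:
            node.support = 1.0  # the root clade is trivially present
            continue
        side = node.leaves if anchor in node.leaves else all_leaves - node.leaves
        node.support = counts.get(frozenset(side), 0) / B
    return tree


def classify_clusters(dendrogram: Dendrogram, k: int) -> pd.Series:
    """Strain → cluster label from the k-cluster cut of the tree."""
    return dendrogram.cut(k)


def standardize_genes(matrix: pd.DataFrame) -> pd.DataFrame:
    """Per-gene unit-variance scaling across strains (clustering input)."""
    sd = matrix.std(axis=0, ddof=1)
    keep = sd > 0
    return matrix.loc[:, keep].div(sd[keep], axis=1)
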