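"""UPGMA clustering, annotated sample trees, double clustering, Newick export.

UPGMA (unweighted pair group method with arithmetic mean) repeatedly merges
the closest pair of clusters; the distance from a merged cluster to any other
is the size-weighted arithmetic mean of its members' distances, and a merge at
distance d places the new node at height d/2.  The result is an ultrametric
binary tree: all leaves sit at height 0, merge heights never decrease, and the
tree distance between two leaves is twice the height of their lowest common
ancestor.

Ties between equally close pairs are broken by the lexicographically smallest
(i, j) cluster-index pair, so output is fully deterministic.

Sample trees built from a catalog carry two per-node annotations: the cosine
similarity between the summed count vectors of the node's two child clusters,
and the total mutation count of the samples beneath the node.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .catalog import MutationalCatalog
from .errors import ValidationError
from .refit import ExposureResult
from .similarity import DistanceMatrix, cosine_similarity, pairwise_cosine_distance


@dataclass(frozen=True)
class MergeNode:
    """One internal node: children are node indices (< n_leaves ⇒ leaf)."""

    left: int
    right: int
    height: float


@dataclass
class ClusterTree:
    """Binary UPGMA merge tree over labelled leaves.

    Internal node i (0-based position in ``merges``) has tree index
    ``n_leaves + i``; a child index below ``n_leaves`` refers to a leaf.
    ``similarity`` and ``mutation_total`` are optional parallel per-internal-
    node annotation lists; ``leaf_totals`` (parallel to ``leaves``) is set
    when mutation totals are annotated.
    """

    leaves: list[str]
    merges: list[MergeNode]
    similarity: list[float] | None = None
    mutation_total: list[int] | None = None
    leaf_totals: list[int] | None = None
    _members: list[frozenset[int]] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        n = len(self.leaves)
        if len(set(self.leaves)) != n:
            raise ValidationError("duplicate leaf ids")
        if len(self.merges) != n - 1:
            raise ValidationError(
                f"expected {n - 1} merges for {n} leaves, got {len(self.merges)}"
            )
        members: list[frozenset[int]] = [frozenset([i]) for i in range(n)]
        last_h = 0.0
        for node in self.merges:
            for c in (node.left, node.right):
                if not 0 <= c < len(members):
                    raise ValidationError(f"child index {c} out of range")
            if node.height < last_h - 1e-12:
                raise ValidationError("merge heights must be non-decreasing")
            last_h = max(last_h, node.height)
            merged = members[node.left] | members[node.right]
            if len(merged) != len(members[node.left]) + len(members[node.right]):
                raise ValidationError("children of a merge must be disjoint")
            members.append(merged)
        if self.merges and len(members[-1]) != n:
            raise ValidationError("root does not cover all leaves")
        for ann, name in ((self.similarity, "similarity"),
                          (self.mutation_total, "mutation_total")):
            if ann is not None and len(ann) != len(self.merges):
                raise ValidationError(f"{name} annotation length mismatch")
        self._members = members

    @property
    def n_leaves(self) -> int:
        return len(self.leaves)

    def members(self, node_index: int) -> frozenset[int]:
        """Leaf-index set under a node (tree indexing: leaves then merges)."""
        return self._members[node_index]

    @property
    def root_index(self) -> int:
        return self.n_leaves + len(self.merges) - 1

    def node_height(self, node_index: int) -> float:
        if node_index < self.n_leaves:
            return 0.0
        return self.merges[node_index - self.n_leaves].height

    def leaf_order(self) -> list[str]:
        """Left-to-right leaf sequence of the merge tree (heatmap ordering)."""
        if not self.merges:
            return list(self.leaves)
        order: list[str] = []
        stack = [self.root_index]
        while stack:
            idx = stack.pop()
            if idx < self.n_leaves:
                order.append(self.leaves[idx])
            else:
                node = self.merges[idx - self.n_leaves]
                stack.append(node.right)
                stack.append(node.left)
        return order

    def cophenetic_distance(self, leaf_a: str, leaf_b: str) -> float:
        """Tree distance between two leaves: 2 × height of their LCA."""
        ia, ib = self.leaves.index(leaf_a), self.leaves.index(leaf_b)
        if ia == ib:
            return 0.0
        for pos, node in enumerate(self.merges):
            m = self._members[self.n_leaves + pos]
            if ia in m and ib in m:
                return 2.0 * node.height
        raise ValidationError("leaves never merge — malformed tree")

    def to_dict(self) -> dict:
        """Nested {id, height, similarity, mutation_total, children} export."""

        def build(idx: int) -> dict:
            if idx < self.n_leaves:
                d: dict = {"id": self.leaves[idx], "height": 0.0}
                if self.leaf_totals is not None:
                    d["mutation_total"] = int(self.leaf_totals[idx])
                return d
            pos = idx - self.n_leaves
            node = self.merges[pos]
            d = {"id": f"node{pos}", "height": node.height,
                 "children": [build(node.left), build(node.right)]}
            if self.similarity is not None:
                d["similarity"] = self.similarity[pos]
            if self.mutation_total is not None:
                d["mutation_total"] = int(self.mutation_total[pos])
            return d

        return build(self.root_index)

    def write_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2)
            fh.write("\n")


def upgma(dist: DistanceMatrix) -> ClusterTree:
    """Cluster a distance matrix with classic UPGMA.

    Merged-cluster distances are size-weighted means; node height is half the
    merging distance; among equally close pairs the lexicographically smallest
    index pair merges first.
    """
    n = len(dist)
    if n < 2:
        raise ValidationError("UPGMA needs at least 2 items")
    if not np.all(np.isfinite(dist.values)):
        raise ValidationError("NaN or infinite distance")

    # active clusters keyed by tree index; D holds current pairwise distances
    D: dict[tuple[int, int], float] = {}
    for i in range(n):
        for j in range(i + 1, n):
            D[(i, j)] = float(dist.values[i, j])
    sizes = {i: 1 for i in range(n)}
    active = set(range(n))
    merges: list[MergeNode] = []
    next_index = n
    while len(active) > 1:
        (i, j) = min(D, key=lambda p: (D[p], p))
        d_min = D[(i, j)]
        merges.append(MergeNode(left=i, right=j, height=d_min / 2.0))
        si, sj = sizes[i], sizes[j]
        for k in sorted(active - {i, j}):
            dik = D[tuple(sorted((i, k)))]
            djk = D[tuple(sorted((j, k)))]
            D[(k, next_index)] = (si * dik + sj * djk) / (si + sj)
        for key in [p for p in D if i in p or j in p]:
            del D[key]
        active -= {i, j}
        active.add(next_index)
        sizes[next_index] = si + sj
        next_index += 1
    return ClusterTree(leaves=list(dist.ids), merges=merges)


def _annotate(tree: ClusterTree, vectors: np.ndarray,
              totals: np.ndarray | None = None) -> None:
    """Attach per-node cosine similarity (between child aggregate vectors)
    and, when ``totals`` is given, mutation totals."""
    n = tree.n_leaves
    agg = [vectors[i].astype(float) for i in range(n)]
    sims: list[float] = []
    for node in tree.merges:
        left, right = agg[node.left], agg[node.right]
        sims.append(cosine_similarity(left, right))
        agg.append(left + right)
    tree.similarity = sims
    if totals is not None:
        node_tot = [int(totals[i]) for i in range(n)]
        for node in tree.merges:
            node_tot.append(node_tot[node.left] + node_tot[node.right])
        tree.leaf_totals = node_tot[:n]
        tree.mutation_total = node_tot[n:]


def sample_tree(catalog: MutationalCatalog) -> ClusterTree:
    """UPGMA tree of a catalog's samples on cosine distance between spectra.

    Each internal node is annotated with the cosine similarity between its
    two child clusters' summed raw count vectors and with the total mutation
    count of the samples beneath it.
    """
    if catalog.n_samples < 2:
        raise ValidationError("sample tree needs at least 2 samples")
    totals = catalog.totals().astype(float)
    spectra = np.divide(
        catalog.counts.astype(float),
        np.where(totals > 0, totals, 1.0)[:, None],
    )
    tree = upgma(pairwise_cosine_distance(spectra, ids=list(catalog.sample_ids)))
    _annotate(tree, catalog.counts, totals=catalog.totals())
    return tree


def double_cluster(
    result: ExposureResult,
) -> tuple[ClusterTree, ClusterTree, list[str], list[str]]:
    """Independently cluster exposure rows (samples) and columns (signatures).

    Returns ``(sample_tree, signature_tree, sample_order, signature_order)``;
    the orders are the left-to-right leaf sequences used to sort an exposure
    heatmap.  Node similarities are annotated from summed exposure vectors.
    """
    if len(result.sample_ids) < 2 or len(result.signature_ids) < 2:
        raise ValidationError("double clustering needs ≥2 samples and ≥2 signatures")
    s_tree = upgma(
        pairwise_cosine_distance(result.exposures, ids=list(result.sample_ids))
    )
    _annotate(s_tree, result.exposures)
    g_tree = upgma(
        pairwise_cosine_distance(result.exposures.T, ids=list(result.signature_ids))
    )
    _annotate(g_tree, result.exposures.T)
    return s_tree, g_tree, s_tree.leaf_order(), g_tree.leaf_order()


def to_newick(tree: ClusterTree) -> str:
    """Serialize a tree as Newick with heights encoded in branch lengths.

    Branch length = parent height − child height (leaves sit at height 0), so
    the tree is ultrametric by construction; internal nodes are labelled with
    their cosine-similarity annotation to 4 decimals when present.
    """

    def label(pos: int) -> str:
        if tree.similarity is None:
            return ""
        return f"{tree.similarity[pos]:.4f}"

    def build(idx: int, parent_height: float) -> str:
        length = parent_height - tree.node_height(idx)
        if idx < tree.n_leaves:
            return f"{tree.leaves[idx]}:{length:.10g}"
        pos = idx - tree.n_leaves
        node = tree.merges[pos]
        inner = (
            f"({build(node.left, node.height)},{build(node.right, node.height)})"
            f"{label(pos)}"
        )
        return inner if idx == tree.root_index else f"{inner}:{length:.10g}"

    return build(tree.root_index, tree.node_height(tree.root_index)) + ";"
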