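"""UPGMA agglomerative clustering on distance matrices.

UPGMA (unweighted pair-group method with arithmetic mean) repeatedly
merges the closest pair of clusters; the distance from a merged cluster
to any other is the size-weighted arithmetic mean of its members'
distances.  The result is a rooted ultrametric tree: every node carries
a height equal to half the merge distance, all leaves sit at height 0,
and every root-to-leaf path has the same length.

Ties between equally close pairs are broken deterministically: each
cluster is keyed by its smallest member label (in sorted label order)
and the lexicographically smallest key pair is merged first, so results
are identical across platforms and input orderings.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError
from .similarity import SymmetricMatrix


@dataclass
class TreeNode:
    """Node of a rooted tree; leaves have a label, internal nodes children."""

    height: float
    children: list["TreeNode"] = field(default_factory=list)
    label: str | None = None
    support: float | None = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf:
            return [self]
        out: list[TreeNode] = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def leaf_labels(self) -> list[str]:
        return [n.label for n in self.leaves()]


@dataclass
class UltrametricTree:
    """Rooted tree with node heights (merge distance / 2)."""

    root: TreeNode

    @property
    def leaf_labels(self) -> list[str]:
        return self.root.leaf_labels()

    def clades(self, include_root: bool = True) -> dict[frozenset, TreeNode]:
        """Internal nodes keyed by their leaf-label set."""
        out: dict[frozenset, TreeNode] = {}

        def walk(node: TreeNode) -> frozenset:
            if node.is_leaf:
                return frozenset([node.label])
            s = frozenset().union(*(walk(c) for c in node.children))
            out[s] = node
            return s

        full = walk(self.root)
        if not include_root:
            out.pop(full, None)
        return out

    def max_height_imbalance(self) -> float:
        """Max |root-to-leaf path difference|; 0 for an exact ultrametric."""

        def depths(node: TreeNode, acc: float) -> list[float]:
            if node.is_leaf:
                return [acc]
            return [
                d
                for c in node.children
                for d in depths(c, acc + (node.height - c.height))
            ]

        ds = depths(self.root, 0.0)
        return max(ds) - min(ds)

    def to_newick(self, *, with_support: bool = False, decimals: int = 6) -> str:
        def quote(label: str) -> str:
            if any(ch in label for ch in " ,();:'\t"):
                return "'" + label.replace("'", "''") + "'"
            return label

        def render(node: TreeNode, parent_height: float | None) -> str:
            if node.is_leaf:
                s = quote(node.label)
            else:
                s = "(" + ",".join(render(c, node.height) for c in node.children) + ")"
                if with_support and node.support is not None:
                    s += f"{node.support:g}"
            if parent_height is not None:
                s += f":{parent_height - node.height:.{decimals}f}"
            return s

        return render(self.root, None) + ";"


def _validate_distance(D: SymmetricMatrix) -> None:
    if D.kind != "distance":
        raise ValidationError("UPGMA needs a distance matrix")
    if len(D.labels) < 2:
        raise ValidationError("need at least two labels")
    if np.isnan(D.values).any():
        raise ValidationError("distance matrix contains NaN")


def upgma(D: SymmetricMatrix) -> UltrametricTree:
    """Build the UPGMA tree of a distance matrix (deterministic tie rule)."""
    _validate_distance(D)
    order = {lab: i for i, lab in enumerate(sorted(D.labels))}
    # active clusters: id -> (node, size, key); key = smallest member label rank
    nodes = {
        i: (TreeNode(0.0, label=lab), 1, order[lab])
        for i, lab in enumerate(D.labels)
    }
    dist: dict[tuple[int, int], float] = {}
    n = len(D.labels)
    for i in range(n):
        for j in range(i + 1, n):
            dist[(i, j)] = float(D.values[i, j])
    next_id = n
    while len(nodes) > 1:
        dmin = min(dist.values())
        best = min(
            (
                tuple(sorted((nodes[i][2], nodes[j][2]))) + (i, j)
                for (i, j), d in dist.items()
                if d == dmin
            )
        )
        i, j = best[2], best[3]
        node_i, size_i, key_i = nodes.pop(i)
        node_j, size_j, key_j = nodes.pop(j)
        if key_j < key_i:  # canonical child order: smaller label rank first
            node_i, node_j = node_j, node_i
        merged = TreeNode(dmin / 2.0, children=[node_i, node_j])
        # size-weighted mean distance to every remaining cluster
        new_dists = {}
        for k in nodes:
            dik = dist.pop(tuple(sorted((i, k))))
            djk = dist.pop(tuple(sorted((j, k))))
            new_dists[k] = (size_i * dik + size_j * djk) / (size_i + size_j)
        del dist[(i, j)]
        nodes[next_id] = (merged, size_i + size_j, min(key_i, key_j))
        for k, d in new_dists.items():
            dist[tuple(sorted((next_id, k)))] = d
        next_id += 1
    (root, _, _), = nodes.values()
    return UltrametricTree(root)


def cophenetic(tree: UltrametricTree) -> SymmetricMatrix:
    """Cophenetic distances: d(i,j) = 2 x height of the LCA of i and j."""
    labels = tree.leaf_labels
    idx = {lab: k for k, lab in enumerate(labels)}
    n = len(labels)
    M = np.zeros((n, n))

    def walk(node: TreeNode) -> list[str]:
        if node.is_leaf:
            return [node.label]
        groups = [walk(c) for c in node.children]
        for gi in range(len(groups)):
            for gj in range(gi + 1, len(groups)):
                for a in groups[gi]:
                    for b in groups[gj]:
                        M[idx[a], idx[b]] = M[idx[b], idx[a]] = 2.0 * node.height
        return [lab for g in groups for lab in g]

    walk(tree.root)
    return SymmetricMatrix(labels, M, "distance")


def _euclidean_rows(M: np.ndarray, labels: list[str]) -> SymmetricMatrix:
    diff = M[:, None, :] - M[None, :, :]
    return SymmetricMatrix(labels, np.sqrt((diff ** 2).sum(axis=2)), "distance")


def heatmap_order(
    M, row_metric: str = "euclidean", col_metric: str = "euclidean"
) -> tuple[list[int], list[int]]:
    """Leaf orders of UPGMA dendrograms on the rows and on the columns.

    Returns (row order, column order) as index lists — the permutation a
    clustered heatmap would display.  Metric: "euclidean" on the raw
    values, or "dice" (binary matrices only) using 1 - similarity.
    """
    import pandas as pd

    from .similarity import similarity_matrix, similarity_to_distance

    if isinstance(M, pd.DataFrame):
        M = M.to_numpy()
    M = np.asarray(M, dtype=float)

    def axis_order(A: np.ndarray, metric: str) -> list[int]:
        labels = [str(i) for i in range(A.shape[0])]
        if A.shape[0] == 1:
            return [0]
        if metric == "euclidean":
            D = _euclidean_rows(A, labels)
        elif metric == "dice":
            D = similarity_to_distance(similarity_matrix(A.astype(int), labels))
        else:
            raise ValidationError(f"unknown heatmap metric: {metric!r}")
        return [int(lab) for lab in upgma(D).leaf_labels]

    return axis_order(M, row_metric), axis_order(M.T, col_metric)
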