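"""Column-bootstrap support for distance trees and majority-rule consensus.

The distance bootstrap resamples alignment columns with replacement,
recomputes the distance matrix and the UPGMA tree for each replicate,
and scores every internal clade of the reference tree by the percentage
of replicate trees that contain the same leaf set as a clade.  Support
is defined on *rooted* clades (the leaf set below a node), matching
UPGMA's rooted output.  Replicates whose distance matrix contains a
saturated pair are skipped, with the skip count reported and the
support denominator adjusted.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .barcode import Alignment, distance_matrix
from .cluster import TreeNode, UltrametricTree, upgma
from .errors import SaturationError, ValidationError


@dataclass
class BootstrapConfig:
    n_replicates: int = 500
    seed: int = 0
    model: str = "jc69"
    deletion: str = "pairwise"

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise ValidationError("n_replicates must be >= 1")


@dataclass
class CladeSupport:
    """Support percentages for each internal clade of a reference tree."""

    supports: dict[frozenset, float]
    n_replicates_used: int
    n_replicates_skipped: int

    def annotate(self, tree: UltrametricTree) -> UltrametricTree:
        """Write supports onto the matching nodes of *tree* (in place)."""
        for leafset, node in tree.clades().items():
            if leafset in self.supports:
                node.support = self.supports[leafset]
        return tree


def bootstrap_resample(aln: Alignment, seed) -> Alignment:
    """Resample alignment columns with replacement (same dimensions).

    *seed* may be an int or a numpy Generator; an int gives a
    reproducible standalone replicate.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    L = aln.length
    cols = rng.integers(0, L, size=L)
    arr = aln.to_array()[:, cols]
    return Alignment(list(aln.labels), ["".join(row) for row in arr])


def clade_support(
    reference: UltrametricTree, aln: Alignment, cfg: BootstrapConfig
) -> CladeSupport:
    """Bootstrap support for every internal clade of *reference*.

    The reference must have been built from the same alignment, model
    and deletion policy, so its leaf set equals the alignment's labels.
    """
    if set(reference.leaf_labels) != set(aln.labels):
        raise ValidationError("reference tree leaves do not match alignment labels")
    ref_clades = list(reference.clades().keys())
    rng = np.random.default_rng(cfg.seed)
    counts = Counter()
    used = skipped = 0
    for _ in range(cfg.n_replicates):
        rep = bootstrap_resample(aln, rng)
        try:
            D = distance_matrix(rep, cfg.model, cfg.deletion)
        except SaturationError:
            skipped += 1
            continue
        rep_clades = set(upgma(D).clades().keys())
        used += 1
        for c in ref_clades:
            if c in rep_clades:
                counts[c] += 1
    if used == 0:
        raise ValidationError("every bootstrap replicate was saturated")
    return CladeSupport(
        supports={c: 100.0 * counts[c] / used for c in ref_clades},
        n_replicates_used=used,
        n_replicates_skipped=skipped,
    )


# ---------------------------------------------------------------------------
# Majority-rule consensus


def majority_consensus(
    trees: list[UltrametricTree], threshold: float = 0.5
) -> UltrametricTree:
    """Greedy majority-rule consensus of rooted trees sharing a leaf set.

    Clades occurring in more than ``threshold`` of the trees (at
    threshold 1.0: in every tree) are added greedily in order of
    decreasing frequency, keeping only clades compatible (nested or
    disjoint) with those already accepted.  Node supports carry the
    occurrence percentage; node heights are not meaningful (the output
    is a topology) and are set to nesting depth.
    """
    if not trees:
        raise ValidationError("empty tree list")
    if not 0.5 <= threshold <= 1.0:
        raise ValidationError("threshold must be in [0.5, 1.0]")
    leafset = frozenset(trees[0].leaf_labels)
    counts = Counter()
    for t in trees:
        if frozenset(t.leaf_labels) != leafset:
            raise ValidationError("trees have mismatched leaf sets")
        for c in t.clades():
            counts[c] += 1
    n = len(trees)
    if threshold == 1.0:
        candidates = {c: k for c, k in counts.items() if k == n}
    else:
        candidates = {c: k for c, k in counts.items() if k / n > threshold}
    candidates[leafset] = counts.get(leafset, n)  # root clade always present

    accepted: list[frozenset] = []
    for c, _ in sorted(
        candidates.items(), key=lambda kv: (-kv[1], -len(kv[0]), sorted(kv[0]))
    ):
        if all(c <= a or a <= c or not (c & a) for a in accepted):
            accepted.append(c)

    support = {c: 100.0 * counts.get(c, n) / n for c in accepted}
    return _tree_from_clades(leafset, accepted, support)


def _tree_from_clades(
    leafset: frozenset, clades: list[frozenset], support: dict[frozenset, float]
) -> UltrametricTree:
    children_of: dict[frozenset, list[frozenset]] = {c: [] for c in clades}
    by_size = sorted(clades, key=len)
    for c in by_size:
        if c == leafset:
            continue
        parent = min(
            (a for a in clades if c < a), key=len
        )
        children_of[parent].append(c)

    def build(c: frozenset) -> TreeNode:
        covered = frozenset().union(*children_of[c]) if children_of[c] else frozenset()
        kids = [build(k) for k in sorted(children_of[c], key=lambda s: sorted(s))]
        kids += [TreeNode(0.0, label=lab) for lab in sorted(c - covered)]
        if len(kids) == 1 and kids[0].is_leaf and len(c) == 1:
            return kids[0]
        h = 1.0 + max((k.height for k in kids), default=0.0)
        return TreeNode(h, children=kids, support=support.get(c))

    return UltrametricTree(build(leafset))
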