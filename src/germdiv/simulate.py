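"""Synthetic inputs with the statistical structure the analyses assume.

Three generators, each a pure function of its config (seed included):

* band matrices — per-primer dominant-marker fingerprints over a set of
  accessions, each band present in an accession independently with its
  own frequency.  Defaults emulate a 12-accession study scored with 11
  primers yielding 97 bands of which 12 are monomorphic.
* alignments — sequences evolved site-independently under the
  Jukes-Cantor (JC69) model along an ultrametric tree with branch
  lengths in substitutions/site; optional masking of cells to 'N'.
* trait matrices — group-structured two-state characters (each cultivar
  is its group prototype with trait states flipped at a small
  probability), so clustering recovery is testable.

Every generator uses a single numpy Generator seeded from its config.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .barcode import Alignment
from .cluster import TreeNode, UltrametricTree
from .errors import ValidationError
from .marker import BandMatrix
from .traits import TraitMatrix

# Per-primer (n_bands, n_monomorphic) emulating an 11-primer, 97-band,
# 12-accession dominant-marker study.
DEFAULT_PRIMER_PLAN = (
    ("P01", 9, 1), ("P02", 11, 0), ("P03", 13, 3), ("P04", 14, 0),
    ("P05", 9, 2), ("P06", 3, 2), ("P07", 21, 0), ("P08", 4, 0),
    ("P09", 4, 2), ("P10", 5, 0), ("P11", 4, 2),
)


@dataclass
class MarkerSimConfig:
    n_accessions: int = 12
    # (primer name, n_bands, n_monomorphic); monomorphic bands get p=1
    primers: tuple = DEFAULT_PRIMER_PLAN
    frequency_range: tuple[float, float] = (0.15, 0.85)
    frequencies: list[float] | None = None  # explicit per-band list overrides
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_accessions < 1:
            raise ValidationError("n_accessions must be >= 1")
        lo, hi = self.frequency_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValidationError("frequency_range must be within [0, 1]")
        for name, n_bands, n_mono in self.primers:
            if n_bands < 1 or not 0 <= n_mono <= n_bands:
                raise ValidationError(f"bad band counts for primer {name!r}")


def simulate_band_matrix(cfg: MarkerSimConfig) -> BandMatrix:
    """Draw a binary band matrix; presence ~ Bernoulli(band frequency)."""
    rng = np.random.default_rng(cfg.seed)
    band_ids, primer_of_band, freqs = [], {}, []
    k = 0
    for name, n_bands, n_mono in cfg.primers:
        for b in range(n_bands):
            bid = f"{name}_b{b + 1}"
            band_ids.append(bid)
            primer_of_band[bid] = name
            if b < n_mono:
                freqs.append(1.0)
            elif cfg.frequencies is not None:
                freqs.append(cfg.frequencies[k])
            else:
                freqs.append(rng.uniform(*cfg.frequency_range))
            k += 1
    p = np.array(freqs)
    values = (rng.random((cfg.n_accessions, len(band_ids))) < p).astype(np.int8)
    accessions = [f"ACC{i + 1:02d}" for i in range(cfg.n_accessions)]
    return BandMatrix(accessions, band_ids, primer_of_band, values)


# ---------------------------------------------------------------------------
# Sequence evolution under JC69


def balanced_coalescent_tree(n_leaves: int = 8, root_height: float = 0.02,
                             prefix: str = "CV") -> UltrametricTree:
    """A simple ultrametric tree: leaves merged pairwise at evenly spaced
    heights up to *root_height* (substitutions/site).  Serves as a
    default genealogy for barcode-scale simulations."""
    if n_leaves < 2:
        raise ValidationError("need >= 2 leaves")
    nodes = [TreeNode(0.0, label=f"{prefix}{i + 1}") for i in range(n_leaves)]
    heights = np.linspace(root_height / (n_leaves - 1), root_height, n_leaves - 1)
    for h in heights:
        a = nodes.pop(0)
        b = nodes.pop(0)
        nodes.append(TreeNode(float(h), children=[a, b]))
    return UltrametricTree(nodes[0])


@dataclass
class SeqSimConfig:
    tree: UltrametricTree = field(default_factory=balanced_coalescent_tree)
    length: int = 700
    missing_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValidationError("length must be >= 1")
        if not 0.0 <= self.missing_fraction < 1.0:
            raise ValidationError("missing_fraction must be in [0, 1)")


_BASES = np.array(list("ACGT"))


def jc69_substitution_probability(t: float) -> float:
    """Probability a site differs after branch length t (JC69):
    p(t) = (3/4)(1 - exp(-4t/3))."""
    if t < 0:
        raise ValidationError("negative branch length")
    return 0.75 * (1.0 - np.exp(-4.0 * t / 3.0))


def simulate_alignment(cfg: SeqSimConfig) -> Alignment:
    """Evolve a root sequence down the tree under JC69, site-independently."""
    rng = np.random.default_rng(cfg.seed)
    root_seq = rng.integers(0, 4, size=cfg.length)
    labels, rows = [], []

    def evolve(node: TreeNode, seq: np.ndarray, parent_height: float) -> None:
        t = parent_height - node.height
        if t < -1e-12:
            raise ValidationError("child higher than parent in tree")
        p_sub = jc69_substitution_probability(max(t, 0.0))
        out = seq.copy()
        hit = rng.random(cfg.length) < p_sub
        n_hit = int(hit.sum())
        if n_hit:
            out[hit] = (out[hit] + rng.integers(1, 4, size=n_hit)) % 4
        if node.is_leaf:
            labels.append(node.label)
            rows.append(out)
        else:
            for c in node.children:
                evolve(c, out, node.height)

    root = cfg.tree.root
    for c in root.children:
        evolve(c, root_seq, root.height)
    if not root.children:
        raise ValidationError("tree has a single leaf")
    chars = _BASES[np.array(rows)]
    if cfg.missing_fraction > 0:
        mask = rng.random(chars.shape) < cfg.missing_fraction
        chars[mask] = "N"
    return Alignment(labels, ["".join(r) for r in chars])


def alignment_with_site_counts(
    n_seqs: int,
    length: int,
    n_variable: int,
    n_parsimony_informative: int,
    n_undetermined: int = 0,
    seed: int = 0,
) -> Alignment:
    """Construct an alignment with exact site-class and missing-cell counts.

    Useful for checking the site-statistics report against known totals:
    *n_parsimony_informative* columns carry two states twice or more,
    the remaining variable columns carry a singleton state, and
    *n_undetermined* cells of 'N' are packed into constant columns.
    """
    if not 0 <= n_parsimony_informative <= n_variable <= length:
        raise ValidationError("need 0 <= PIS <= variable <= length")
    if n_seqs < 4:
        raise ValidationError("need >= 4 sequences to host informative sites")
    if n_undetermined > (length - n_variable) * n_seqs:
        raise ValidationError("too many undetermined cells for the constant columns")
    rng = np.random.default_rng(seed)
    arr = np.full((n_seqs, length), "A")
    cols = rng.permutation(length)
    pis_cols = cols[:n_parsimony_informative]
    singleton_cols = cols[n_parsimony_informative:n_variable]
    constant_cols = cols[n_variable:]
    arr[:2, pis_cols] = "T"
    arr[0, singleton_cols] = "T"
    placed = 0
    for c in constant_cols:
        if placed >= n_undetermined:
            break
        take = min(n_seqs, n_undetermined - placed)
        arr[:take, c] = "N"
        placed += take
    labels = [f"SEQ{i + 1}" for i in range(n_seqs)]
    return Alignment(labels, ["".join(r) for r in arr])


# ---------------------------------------------------------------------------
# Group-structured traits


@dataclass
class TraitSimConfig:
    n_cultivars: int = 8
    n_traits: int = 15
    n_groups: int = 2
    within_flip: float = 0.1
    separation: float = 0.5  # fraction of traits on which prototypes differ
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_groups < 1 or self.n_cultivars < self.n_groups:
            raise ValidationError("need n_cultivars >= n_groups >= 1")
        if not 0.0 <= self.within_flip <= 1.0 or not 0.0 <= self.separation <= 1.0:
            raise ValidationError("probabilities must be in [0, 1]")


def simulate_trait_matrix(cfg: TraitSimConfig) -> TraitMatrix:
    """Binary traits around group prototypes.

    Prototypes differ from a common base on round(separation * n_traits)
    randomly chosen traits; each cultivar flips each trait of its group
    prototype independently with probability *within_flip*, so expected
    within-group disagreement is below between-group disagreement
    whenever within_flip < separation / 2.
    """
    rng = np.random.default_rng(cfg.seed)
    base = rng.integers(0, 2, size=cfg.n_traits)
    n_diff = round(cfg.separation * cfg.n_traits)
    prototypes = [base]
    for _ in range(1, cfg.n_groups):
        proto = base.copy()
        flip = rng.choice(cfg.n_traits, size=n_diff, replace=False)
        proto[flip] ^= 1
        prototypes.append(proto)
    labels, rows = [], []
    for i in range(cfg.n_cultivars):
        g = i % cfg.n_groups
        noise = rng.random(cfg.n_traits) < cfg.within_flip
        rows.append(prototypes[g] ^ noise.astype(int))
        labels.append(f"G{g + 1}C{i // cfg.n_groups + 1}")
    trait_ids = [f"T{j + 1:02d}" for j in range(cfg.n_traits)]
    return TraitMatrix(labels, trait_ids, np.array(rows))
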