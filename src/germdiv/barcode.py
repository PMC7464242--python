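"""Alignment site statistics and Jukes-Cantor distances for DNA barcodes.

Works on pre-aligned nucleotide sequences (e.g. chloroplast matK and
trnH-psbA barcodes).  A cell is *determined* if it is one of A, C, G, T;
gaps ('-'), 'N', '?' and all partial IUPAC ambiguity codes count as
undetermined, both for the missing-data percentage (undetermined cells /
(length x sequences)) and for site classification and distances.

Site classes (determined residues only):
  constant                <= 1 distinct state
  parsimony-informative   >= 2 states, each in >= 2 sequences
  variable-uninformative  otherwise variable
  undetermined-only       no determined residue at all

Distances: p-distance (mismatch proportion over comparable sites) and
the Jukes-Cantor correction d = -(3/4) ln(1 - (4/3) p), defined for
p < 3/4.  Deletion policies: *pairwise* (per pair, sites where both
residues are determined) or *complete* (sites determined in every
sequence of the alignment).
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from Bio import SeqIO

from ._util import round_half_up
from .errors import NoComparableSitesError, SaturationError, ValidationError

DETERMINED = frozenset("ACGT")
AMBIGUITY = frozenset("RYSWKMBDHV")
ALPHABET = DETERMINED | AMBIGUITY | frozenset("N-?")


@dataclass
class Alignment:
    """Equal-length aligned sequences over the IUPAC DNA alphabet."""

    labels: list[str]
    sequences: list[str]

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.sequences):
            raise ValidationError("labels and sequences differ in count")
        if len(self.sequences) < 2:
            raise ValidationError("alignment needs at least two sequences")
        if len(set(self.labels)) != len(self.labels):
            raise ValidationError("duplicate sequence labels")
        self.sequences = [s.upper() for s in self.sequences]
        L = len(self.sequences[0])
        if L < 1:
            raise ValidationError("alignment length must be >= 1")
        ragged = [
            f"{lab} ({len(s)} vs {L})"
            for lab, s in zip(self.labels, self.sequences)
            if len(s) != L
        ]
        if ragged:
            raise ValidationError(f"ragged alignment, offending record(s): {ragged}")
        for lab, s in zip(self.labels, self.sequences):
            bad = set(s) - ALPHABET
            if bad:
                raise ValidationError(f"record {lab!r} has invalid symbol(s): {sorted(bad)}")

    @property
    def length(self) -> int:
        return len(self.sequences[0])

    @property
    def n_sequences(self) -> int:
        return len(self.sequences)

    def column(self, i: int) -> list[str]:
        return [s[i] for s in self.sequences]

    def to_array(self) -> np.ndarray:
        return np.array([list(s) for s in self.sequences])

    def to_fasta(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for lab, s in zip(self.labels, self.sequences):
                fh.write(f">{lab}\n{s}\n")


def read_alignment(path) -> Alignment:
    """Read an aligned multi-FASTA file."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValidationError(f"no FASTA records in {path}")
    return Alignment([r.id for r in records], [str(r.seq) for r in records])


# ---------------------------------------------------------------------------
# Site statistics

SITE_CLASSES = (
    "constant",
    "variable-uninformative",
    "parsimony-informative",
    "undetermined-only",
)


def classify_site(column) -> str:
    """Classify an alignment column using determined residues only."""
    if not len(column):
        raise ValidationError("empty column")
    counts = Counter(r for r in (c.upper() for c in column) if r in DETERMINED)
    if not counts:
        return "undetermined-only"
    if len(counts) <= 1:
        return "constant"
    if sum(1 for c in counts.values() if c >= 2) >= 2:
        return "parsimony-informative"
    return "variable-uninformative"


@dataclass
class AlignmentStats:
    aligned_length: int
    undetermined_count: int
    missing_percent: float
    variable_sites: int
    prop_variable: float
    parsimony_informative_sites: int
    prop_pis: float
    at_percent: float   # proportion in [0,1] of determined cells that are A/T
    gc_percent: float

    def report(self) -> dict:
        """Rounded as conventionally printed: proportions to 3 decimals,
        missing percent to 2, base composition to 2."""
        return {
            "aligned_length": self.aligned_length,
            "undetermined": self.undetermined_count,
            "missing_percent": round_half_up(self.missing_percent, 2),
            "variable_sites": self.variable_sites,
            "prop_variable": round_half_up(self.prop_variable, 3),
            "parsimony_informative_sites": self.parsimony_informative_sites,
            "prop_pis": round_half_up(self.prop_pis, 3),
            "at_percent": round_half_up(self.at_percent, 2),
            "gc_percent": round_half_up(self.gc_percent, 2),
        }


def alignment_stats(aln: Alignment) -> AlignmentStats:
    """Length, missing data, variable / parsimony-informative site counts
    and pooled base composition of an alignment."""
    arr = aln.to_array()
    determined = np.isin(arr, list(DETERMINED))
    u = int((~determined).sum())
    classes = [classify_site(aln.column(i)) for i in range(aln.length)]
    v = sum(c in ("variable-uninformative", "parsimony-informative") for c in classes)
    k = sum(c == "parsimony-informative" for c in classes)
    det_cells = arr[determined]
    n_det = det_cells.size
    at = int(np.isin(det_cells, ["A", "T"]).sum()) / n_det if n_det else 0.0
    L = aln.length
    return AlignmentStats(
        aligned_length=L,
        undetermined_count=u,
        missing_percent=100.0 * u / (L * aln.n_sequences),
        variable_sites=v,
        prop_variable=v / L,
        parsimony_informative_sites=k,
        prop_pis=k / L,
        at_percent=at,
        gc_percent=1.0 - at if n_det else 0.0,
    )


# ---------------------------------------------------------------------------
# Distances

def _complete_mask(aln: Alignment) -> np.ndarray:
    """Boolean site mask: determined in every sequence."""
    return np.isin(aln.to_array(), list(DETERMINED)).all(axis=0)


def p_distance(
    x: str, y: str, deletion: str = "pairwise", site_mask: np.ndarray | None = None
) -> tuple[float, int]:
    """Mismatch proportion and effective site count for one sequence pair.

    With ``deletion="complete"`` a *site_mask* (from the full alignment)
    restricts the comparison; ``pairwise`` masks per pair.
    """
    if deletion not in ("pairwise", "complete"):
        raise ValidationError(f"unknown deletion policy: {deletion!r}")
    if len(x) != len(y):
        raise ValidationError("sequence length mismatch")
    a = np.array(list(x.upper()))
    b = np.array(list(y.upper()))
    both = np.isin(a, list(DETERMINED)) & np.isin(b, list(DETERMINED))
    if deletion == "complete":
        if site_mask is None:
            raise ValidationError("complete deletion needs the alignment-wide site mask")
        both &= site_mask
    m = int(both.sum())
    if m == 0:
        raise NoComparableSitesError("no comparable determined sites")
    return float((a[both] != b[both]).mean()), m


def jc69(p_hat: float) -> float:
    """Jukes-Cantor distance d = -(3/4) ln(1 - (4/3) p), substitutions/site."""
    if p_hat < 0:
        raise ValidationError(f"negative mismatch proportion: {p_hat}")
    if p_hat >= 0.75:
        raise SaturationError([("p", p_hat)])
    return -0.75 * math.log1p(-(4.0 / 3.0) * p_hat)


def distance_matrix(
    aln: Alignment, model: str = "jc69", deletion: str = "pairwise"
):
    """All pairwise distances under ``model`` in {"p", "jc69"}.

    Raises :class:`SaturationError` listing every saturated pair if the
    JC69 correction is undefined anywhere.
    """
    from .similarity import SymmetricMatrix

    if model not in ("p", "jc69"):
        raise ValidationError(f"unknown model: {model!r}")
    mask = _complete_mask(aln) if deletion == "complete" else None
    n = aln.n_sequences
    M = np.zeros((n, n))
    saturated = []
    for i in range(n):
        for j in range(i + 1, n):
            p_hat, _ = p_distance(aln.sequences[i], aln.sequences[j], deletion, mask)
            if model == "p":
                M[i, j] = M[j, i] = p_hat
            elif p_hat >= 0.75:
                saturated.append((aln.labels[i], aln.labels[j]))
            else:
                M[i, j] = M[j, i] = jc69(p_hat)
    if saturated:
        raise SaturationError(saturated)
    return SymmetricMatrix(list(aln.labels), M, "distance")
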