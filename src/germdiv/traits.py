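"""Two-state morpho-agronomic trait tables: encoding, clustering, ordination.

Morphological descriptors scored as two-state characters (e.g. plant
height < 70 vs >= 70 cm, petiole glabrous vs hairy) are encoded 0/1
against a codebook, clustered with Euclidean distance + UPGMA, and
ordinated with PCA (trait loadings for a biplot) and PCoA.

A reference table for eight alfalfa (*Medicago sativa* L.) cultivars x
15 two-state traits ships with the package (``load_alfalfa_traits``).
The published source of that table prints ">=4" for the terminal-leaflet
length of three cultivars although the trait's states are <20 / >=20;
the bundled codebook records ">=4" as an alias of the high state and
flags it as a transcription anomaly.  Encoding is orientation-invariant:
flipping every trait's 0/1 assignment leaves all distances unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .cluster import UltrametricTree, upgma
from .errors import ValidationError
from .ordination import OrdinationResult, pca_binary, pcoa
from .similarity import SymmetricMatrix, euclidean_distance_matrix


@dataclass
class TraitDef:
    abbreviation: str
    name: str
    state0: str
    state1: str
    aliases: dict[str, int] = field(default_factory=dict)  # alias string -> bit
    note: str = ""

    def encode(self, value: str) -> int:
        v = value.strip()
        if v == self.state0:
            return 0
        if v == self.state1:
            return 1
        if v in self.aliases:
            return self.aliases[v]
        raise ValidationError(
            f"unrecognised state {value!r} for trait {self.abbreviation!r} "
            f"(expected {self.state0!r} or {self.state1!r})"
        )

    def decode(self, bit: int) -> str:
        return self.state1 if bit else self.state0


@dataclass
class TraitCodebook:
    traits: dict[str, TraitDef]  # abbreviation -> definition, ordered

    def __post_init__(self) -> None:
        if not self.traits:
            raise ValidationError("empty codebook")

    def __getitem__(self, abbrev: str) -> TraitDef:
        try:
            return self.traits[abbrev]
        except KeyError:
            raise ValidationError(f"trait {abbrev!r} not in codebook") from None


@dataclass
class TraitMatrix:
    """Cultivars x traits, binary."""

    cultivar_ids: list[str]
    trait_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.shape != (len(self.cultivar_ids), len(self.trait_ids)):
            raise ValidationError("trait matrix shape mismatch")
        if not np.isin(self.values, (0, 1)).all():
            raise ValidationError("trait matrix must be binary (0/1)")
        self.values = self.values.astype(np.int8)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.cultivar_ids, columns=self.trait_ids)


def read_codebook(path) -> TraitCodebook:
    """Read a codebook TSV: abbreviation, name, state0, state1,
    optional comma-separated state1_aliases, optional note."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    traits: dict[str, TraitDef] = {}
    for _, row in df.iterrows():
        ab = row["abbreviation"].strip()
        if ab in traits:
            raise ValidationError(f"duplicate trait abbreviation {ab!r}")
        aliases = {
            a.strip(): 1
            for a in str(row.get("state1_aliases", "")).split(",")
            if a.strip()
        }
        traits[ab] = TraitDef(
            ab, row["name"], row["state0"].strip(), row["state1"].strip(),
            aliases, str(row.get("note", "")),
        )
    return TraitCodebook(traits)


def read_trait_table(path) -> pd.DataFrame:
    """Read a state-string table (rows = traits, columns = cultivars) and
    return it transposed: cultivars x traits."""
    df = pd.read_csv(path, sep="\t", dtype=str, index_col=0)
    return df.T


def encode_traits(raw: pd.DataFrame, codebook: TraitCodebook) -> TraitMatrix:
    """Encode a cultivars x traits table of state strings to 0/1."""
    values = np.zeros(raw.shape, dtype=np.int8)
    for j, trait in enumerate(raw.columns):
        tdef = codebook[str(trait)]
        for i, cultivar in enumerate(raw.index):
            try:
                values[i, j] = tdef.encode(str(raw.iloc[i, j]))
            except ValidationError as exc:
                raise ValidationError(f"cultivar {cultivar!r}: {exc}") from None
    return TraitMatrix(list(map(str, raw.index)), list(map(str, raw.columns)), values)


def decode_traits(matrix: TraitMatrix, codebook: TraitCodebook) -> pd.DataFrame:
    """Map bits back to canonical state strings (aliases canonicalised)."""
    out = pd.DataFrame(index=matrix.cultivar_ids, columns=matrix.trait_ids, dtype=object)
    for j, trait in enumerate(matrix.trait_ids):
        tdef = codebook[trait]
        out.iloc[:, j] = [tdef.decode(int(b)) for b in matrix.values[:, j]]
    return out


def load_alfalfa_traits() -> tuple[TraitMatrix, TraitCodebook, pd.DataFrame]:
    """Bundled eight-cultivar alfalfa trait table.

    Returns (encoded matrix, codebook, raw state-string table).
    """
    pkg = resources.files("germdiv") / "data"
    codebook = read_codebook(str(pkg / "alfalfa_trait_codebook.tsv"))
    raw = read_trait_table(str(pkg / "alfalfa_trait_table.tsv"))
    return encode_traits(raw, codebook), codebook, raw


@dataclass
class TraitAnalysis:
    distances: SymmetricMatrix
    tree: UltrametricTree
    pca: OrdinationResult
    pcoa: OrdinationResult


def trait_pipeline(matrix: TraitMatrix) -> TraitAnalysis:
    """Euclidean distance -> UPGMA tree, plus PCA (biplot loadings,
    default ordination route) and PCoA of the same distances."""
    if len(matrix.cultivar_ids) < 2:
        raise ValidationError("need at least two cultivars")
    D = euclidean_distance_matrix(matrix.values, labels=matrix.cultivar_ids)
    return TraitAnalysis(
        distances=D,
        tree=upgma(D),
        pca=pca_binary(matrix.to_frame()),
        pcoa=pcoa(D),
    )
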