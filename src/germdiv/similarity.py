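"""Binary similarity coefficients and symmetric similarity/distance matrices.

For two binary fingerprints let a = shared presences, b/c = presences
unique to either, d = shared absences, n = a+b+c+d:

* Dice            2a / (2a + b + c)   — weights shared bands doubly
* Jaccard         a / (a + b + c)
* simple matching (a + d) / n

A pair of all-zero vectors has empty support; by convention its Dice and
Jaccard similarity is 1 (identical absence profiles).  Such pairs are
recorded on the returned matrix as warnings.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError


@dataclass
class SymmetricMatrix:
    """Labelled symmetric matrix, either a similarity or a distance."""

    labels: list[str]
    values: np.ndarray
    kind: str  # "similarity" | "distance"
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValidationError(f"matrix shape {self.values.shape} vs {n} labels")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValidationError("matrix is not symmetric")
        if self.kind not in ("similarity", "distance"):
            raise ValidationError(f"unknown kind: {self.kind!r}")
        diag = np.diagonal(self.values)
        if self.kind == "similarity":
            if not (np.allclose(diag, 1.0) and (self.values >= -1e-12).all()
                    and (self.values <= 1 + 1e-12).all()):
                raise ValidationError("similarity needs unit diagonal and cells in [0,1]")
        else:
            if not (np.allclose(diag, 0.0) and (self.values >= -1e-12).all()):
                raise ValidationError("distance needs zero diagonal and non-negative cells")

    def __getitem__(self, pair) -> float:
        i, j = (self.labels.index(k) for k in pair)
        return float(self.values[i, j])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def to_phylip(self) -> str:
        """PHYLIP-style square matrix text."""
        lines = [str(len(self.labels))]
        for lab, row in zip(self.labels, self.values):
            lines.append(lab + "\t" + "\t".join(f"{v:.6f}" for v in row))
        return "\n".join(lines) + "\n"


def _abcd(x, y) -> tuple[int, int, int, int]:
    x = np.asarray(x)
    y = np.asarray(y)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError(f"vector length mismatch: {x.shape} vs {y.shape}")
    for v in (x, y):
        if not np.isin(v, (0, 1)).all():
            raise ValidationError("vectors must be binary (0/1)")
    a = int(((x == 1) & (y == 1)).sum())
    b = int(((x == 1) & (y == 0)).sum())
    c = int(((x == 0) & (y == 1)).sum())
    return a, b, c, len(x) - a - b - c


def dice_similarity(x, y) -> float:
    """Dice coefficient 2a/(2a+b+c); 1 for two all-zero vectors."""
    a, b, c, _ = _abcd(x, y)
    if a + b + c == 0:
        return 1.0
    return 2 * a / (2 * a + b + c)


def jaccard_similarity(x, y) -> float:
    """Jaccard coefficient a/(a+b+c); 1 for two all-zero vectors."""
    a, b, c, _ = _abcd(x, y)
    if a + b + c == 0:
        return 1.0
    return a / (a + b + c)


def simple_matching(x, y) -> float:
    """Simple matching coefficient (a+d)/n."""
    a, b, c, d = _abcd(x, y)
    return (a + d) / (a + b + c + d)


_COEFFICIENTS = {
    "dice": dice_similarity,
    "jaccard": jaccard_similarity,
    "simple_matching": simple_matching,
}


def similarity_matrix(matrix, labels=None, coefficient: str = "dice") -> SymmetricMatrix:
    """Pairwise similarity of the rows of a binary matrix.

    *matrix* may be a 2-D array, a DataFrame (index used as labels) or a
    :class:`~germdiv.marker.BandMatrix`.
    """
    if hasattr(matrix, "accession_ids"):  # BandMatrix
        labels = labels or list(matrix.accession_ids)
        matrix = matrix.values
    elif isinstance(matrix, pd.DataFrame):
        labels = labels or [str(i) for i in matrix.index]
        matrix = matrix.to_numpy()
    M = np.asarray(matrix)
    if labels is None:
        labels = [f"row{i}" for i in range(M.shape[0])]
    try:
        fn = _COEFFICIENTS[coefficient]
    except KeyError:
        raise ValidationError(f"unknown coefficient: {coefficient!r}") from None
    n = M.shape[0]
    S = np.eye(n)
    warns: list[str] = []
    for i in range(n):
        for j in range(i + 1, n):
            S[i, j] = S[j, i] = fn(M[i], M[j])
            if coefficient in ("dice", "jaccard") and not (M[i].any() or M[j].any()):
                msg = f"all-zero pair {labels[i]}~{labels[j]}: similarity 1 by convention"
                warns.append(msg)
                warnings.warn(msg, stacklevel=2)
    return SymmetricMatrix(list(labels), S, "similarity", warnings=warns)


def similarity_to_distance(S: SymmetricMatrix, transform: str = "one_minus_s") -> SymmetricMatrix:
    """d = 1 - s (default) or d = sqrt(1 - s).

    The sqrt transform makes Dice dissimilarities Euclidean-embeddable,
    which principal-coordinates analysis benefits from.
    """
    if S.kind != "similarity":
        raise ValidationError("input must be a similarity matrix")
    if transform in ("one_minus_s", "one-minus-s"):
        D = 1.0 - S.values
    elif transform in ("sqrt_one_minus_s", "sqrt-one-minus-s"):
        D = np.sqrt(np.clip(1.0 - S.values, 0.0, None))
    else:
        raise ValidationError(f"unknown transform: {transform!r}")
    np.fill_diagonal(D, 0.0)
    return SymmetricMatrix(list(S.labels), D, "distance", warnings=list(S.warnings))


def euclidean_distance_matrix(matrix, labels=None) -> SymmetricMatrix:
    """Pairwise Euclidean distance between binary rows.

    For 0/1 rows this is sqrt(number of traits on which the two rows
    disagree), the metric conventionally paired with UPGMA for
    two-state morphological data.
    """
    if isinstance(matrix, pd.DataFrame):
        labels = labels or [str(i) for i in matrix.index]
        matrix = matrix.to_numpy()
    M = np.asarray(matrix)
    if not np.isin(M, (0, 1)).all():
        raise ValidationError("matrix must be binary (0/1)")
    if M.shape[0] < 2:
        raise ValidationError("need at least two rows")
    if labels is None:
        labels = [f"row{i}" for i in range(M.shape[0])]
    diff = (M[:, None, :] != M[None, :, :]).sum(axis=2)
    return SymmetricMatrix(list(labels), np.sqrt(diff.astype(float)), "distance")
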