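"""Principal coordinates (classical metric scaling) and PCA for binary data.

PCoA embeds a distance matrix: Gower-centre B = -1/2 J D^2 J, take the
eigendecomposition, and scale eigenvectors by sqrt(eigenvalue).  When D
is Euclidean-embeddable the pairwise distances of the coordinates
reproduce D exactly; otherwise negative eigenvalues appear — they are
reported but their axes are dropped.

PCA on a binary matrix column-centres and eigendecomposes the covariance
matrix, returning row scores and column loadings for a biplot.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError
from .similarity import SymmetricMatrix


@dataclass
class OrdinationResult:
    """Coordinates plus the eigen-spectrum behind them."""

    coordinates: pd.DataFrame          # labels x retained axes
    eigenvalues: np.ndarray            # full spectrum, descending
    proportion_explained: np.ndarray   # per retained axis
    loadings: pd.DataFrame | None = None  # variables x axes (PCA biplot only)
    warnings: list[str] = field(default_factory=list)


def pcoa(D: SymmetricMatrix, n_axes: int | None = None) -> OrdinationResult:
    """Classical metric scaling of a distance matrix."""
    if D.kind != "distance":
        raise ValidationError("PCoA needs a distance matrix")
    n = len(D.labels)
    if n < 2:
        raise ValidationError("need at least two labels")
    if n_axes is not None and n_axes > n:
        raise ValidationError(f"n_axes={n_axes} exceeds number of labels {n}")
    A = -0.5 * D.values ** 2
    J = np.eye(n) - np.ones((n, n)) / n
    B = J @ A @ J
    eigvals, eigvecs = np.linalg.eigh((B + B.T) / 2.0)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    tol = 1e-9 * max(1.0, abs(eigvals[0]))
    positive = eigvals > tol
    warns = []
    if (eigvals < -tol).any():
        warns.append(
            f"{int((eigvals < -tol).sum())} negative eigenvalue(s): "
            "distances are not fully Euclidean-embeddable; axes dropped"
        )
    k = int(positive.sum())
    if n_axes is not None:
        k = min(k, n_axes)
    coords = eigvecs[:, :k] * np.sqrt(eigvals[:k])
    total = eigvals[positive].sum()
    prop = eigvals[:k] / total if total > 0 else np.zeros(k)
    return OrdinationResult(
        coordinates=pd.DataFrame(
            coords, index=D.labels, columns=[f"PCo{i+1}" for i in range(k)]
        ),
        eigenvalues=eigvals,
        proportion_explained=prop,
        warnings=warns,
    )


def pca_binary(M, n_axes: int | None = None, labels=None, columns=None) -> OrdinationResult:
    """PCA of a (binary) matrix with loadings for a biplot.

    Columns are centred; the covariance matrix (denominator n-1) is
    eigendecomposed.  A constant matrix has zero total variance: zero
    scores are returned with a warning rather than an error.
    """
    if isinstance(M, pd.DataFrame):
        labels = labels or [str(i) for i in M.index]
        columns = columns or [str(c) for c in M.columns]
        M = M.to_numpy()
    X = np.asarray(M, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValidationError("need a 2-D matrix with at least two rows")
    n, p = X.shape
    if labels is None:
        labels = [f"row{i}" for i in range(n)]
    if columns is None:
        columns = [f"var{j}" for j in range(p)]
    if n_axes is not None and n_axes > min(n, p):
        raise ValidationError(f"n_axes={n_axes} exceeds matrix rank bound {min(n, p)}")
    Xc = X - X.mean(axis=0)
    C = Xc.T @ Xc / (n - 1)
    eigvals, eigvecs = np.linalg.eigh((C + C.T) / 2.0)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = np.clip(eigvals[order], 0.0, None), eigvecs[:, order]
    total = eigvals.sum()
    warns = []
    if total <= 1e-12:
        warns.append("matrix has zero total variance; all scores are zero")
        k = 1 if n_axes is None else n_axes
        return OrdinationResult(
            coordinates=pd.DataFrame(
                np.zeros((n, k)), index=labels, columns=[f"PC{i+1}" for i in range(k)]
            ),
            eigenvalues=eigvals,
            proportion_explained=np.zeros(k),
            loadings=pd.DataFrame(
                eigvecs[:, :k], index=columns, columns=[f"PC{i+1}" for i in range(k)]
            ),
            warnings=warns,
        )
    k = min(n - 1, p) if n_axes is None else n_axes
    axes = [f"PC{i+1}" for i in range(k)]
    return OrdinationResult(
        coordinates=pd.DataFrame(Xc @ eigvecs[:, :k], index=labels, columns=axes),
        eigenvalues=eigvals,
        proportion_explained=eigvals[:k] / total,
        loadings=pd.DataFrame(eigvecs[:, :k], index=columns, columns=axes),
        warnings=warns,
    )
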