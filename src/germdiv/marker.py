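"""Dominant-marker band matrices and primer informativeness statistics.

Dominant multilocus fingerprints (IRAP, ISSR, RAPD, AFLP) are scored as
binary presence/absence matrices: one row per accession, one column per
band, each band amplified by a known primer.  Because the assay cannot
distinguish heterozygotes, all informativeness statistics work on band
frequencies and banding patterns rather than allele frequencies:

* band informativeness  Ib = 1 - 2|0.5 - p|  (p = frequency of accessions
  carrying the band),
* resolving power       Rp = sum of Ib over a primer's bands,
* percent polymorphism  %P = 100 * polymorphic / total bands,
* effective multiplex ratio  EMR = n_poly * (n_poly / n_total),
* polymorphic information content PIC, either as banding-pattern
  diversity 1 - sum(f_i^2) or as mean per-band gene diversity 2p(1-p),
* marker index          MI = PIC * EMR.

Raw (unrounded) values are kept everywhere; rounding happens only when a
report table is rendered.
"""

from __future__ import annotations

import io
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from ._util import round_half_up
from .errors import ValidationError

PIC_VARIANTS = ("pattern_diversity", "mean_band_heterozygosity")


@dataclass
class BandMatrix:
    """Binary accessions x bands matrix with a band -> primer assignment.

    Parameters
    ----------
    accession_ids : unique row labels, order preserved.
    band_ids : unique column labels, order preserved.
    primer_of_band : mapping from every band id to its primer name.
    values : 2-D 0/1 integer array, shape (n_accessions, n_bands).
    """

    accession_ids: list[str]
    band_ids: list[str]
    primer_of_band: dict[str, str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2 or self.values.shape != (
            len(self.accession_ids),
            len(self.band_ids),
        ):
            raise ValidationError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.accession_ids)} accessions x {len(self.band_ids)} bands"
            )
        bad = np.argwhere(~np.isin(self.values, (0, 1)))
        if bad.size:
            i, j = bad[0]
            raise ValidationError(
                f"non-binary cell at accession {self.accession_ids[i]!r}, "
                f"band {self.band_ids[j]!r}: {self.values[i, j]!r}"
            )
        self.values = self.values.astype(np.int8)
        for name, labels in (("accession", self.accession_ids), ("band", self.band_ids)):
            dupes = [k for k, c in Counter(labels).items() if c > 1]
            if dupes:
                raise ValidationError(f"duplicate {name} label(s): {dupes}")
        missing = [b for b in self.band_ids if b not in self.primer_of_band]
        if missing:
            raise ValidationError(f"band(s) without a primer assignment: {missing}")

    # -- convenience -------------------------------------------------------

    @property
    def n_accessions(self) -> int:
        return len(self.accession_ids)

    @property
    def primers(self) -> list[str]:
        """Primer names in first-appearance (column) order."""
        seen: dict[str, None] = {}
        for b in self.band_ids:
            seen.setdefault(self.primer_of_band[b], None)
        return list(seen)

    def bands_of_primer(self, primer: str) -> list[str]:
        bands = [b for b in self.band_ids if self.primer_of_band[b] == primer]
        if not bands:
            raise ValidationError(f"unknown primer: {primer!r}")
        return bands

    def band_column(self, band: str) -> np.ndarray:
        try:
            j = self.band_ids.index(band)
        except ValueError:
            raise ValidationError(f"unknown band: {band!r}") from None
        return self.values[:, j]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.accession_ids, columns=self.band_ids)


@dataclass
class BandStats:
    band_id: str
    p: float
    ib: float
    is_polymorphic: bool


@dataclass
class PrimerSummary:
    """One row of the per-primer informativeness table."""

    primer: str
    n_total: int
    n_mono: int
    n_poly: int
    pct_poly: float
    pic: float
    rp: float
    emr: float
    mi: float


# ---------------------------------------------------------------------------
# I/O

def read_band_matrix(
    path, *, sep: str | None = None, transpose: bool = False
) -> BandMatrix:
    """Read a band matrix from delimited text.

    Layout: first header row = band ids, second header row = primer name of
    each band, then one row per accession (first column = accession id).
    ``transpose=True`` tolerates the other orientation (bands as rows).
    Comma and tab are auto-detected when *sep* is None.
    """
    text = Path(path).read_text(encoding="utf-8")
    if not text.strip():
        raise ValidationError(f"empty band-matrix file: {path}")
    if sep is None:
        first = text.splitlines()[0]
        sep = "\t" if first.count("\t") >= first.count(",") else ","
    rows = [line.split(sep) for line in text.splitlines() if line.strip()]
    if transpose:
        rows = [list(r) for r in zip(*rows)]
    if len(rows) < 3:
        raise ValidationError("band-matrix file needs 2 header rows and >=1 accession row")
    band_ids = [c.strip() for c in rows[0][1:]]
    primer_row = [c.strip() for c in rows[1][1:]]
    if len(primer_row) != len(band_ids):
        raise ValidationError("primer header row length does not match band header")
    accession_ids = [r[0].strip() for r in rows[2:]]
    cells = []
    for r in rows[2:]:
        if len(r) != len(band_ids) + 1:
            raise ValidationError(f"row {r[0]!r} has {len(r) - 1} cells, expected {len(band_ids)}")
        row_vals = []
        for band, cell in zip(band_ids, r[1:]):
            cell = cell.strip()
            if cell not in ("0", "1"):
                raise ValidationError(
                    f"non-binary cell at accession {r[0].strip()!r}, band {band!r}: {cell!r}"
                )
            row_vals.append(int(cell))
        cells.append(row_vals)
    return BandMatrix(
        accession_ids=accession_ids,
        band_ids=band_ids,
        primer_of_band=dict(zip(band_ids, primer_row)),
        values=np.array(cells),
    )


def write_band_matrix(matrix: BandMatrix, path, *, sep: str = "\t") -> None:
    """Write in the layout :func:`read_band_matrix` consumes."""
    buf = io.StringIO()
    buf.write("accession" + sep + sep.join(matrix.band_ids) + "\n")
    buf.write("primer" + sep + sep.join(matrix.primer_of_band[b] for b in matrix.band_ids) + "\n")
    for acc, row in zip(matrix.accession_ids, matrix.values):
        buf.write(acc + sep + sep.join(str(int(v)) for v in row) + "\n")
    Path(path).write_text(buf.getvalue(), encoding="utf-8")


# ---------------------------------------------------------------------------
# Per-band statistics

def band_frequency(matrix: BandMatrix, band: str) -> float:
    """Frequency p of accessions carrying the band (exact ratio)."""
    col = matrix.band_column(band)
    return int(col.sum()) / matrix.n_accessions


def band_informativeness(p: float) -> float:
    """Ib = 1 - 2|0.5 - p|; maximal (1) at p = 0.5, zero for fixed bands."""
    if not 0.0 <= p <= 1.0:
        raise ValidationError(f"band frequency outside [0, 1]: {p}")
    return 1.0 - 2.0 * abs(0.5 - p)


def band_stats(matrix: BandMatrix, band: str) -> BandStats:
    p = band_frequency(matrix, band)
    return BandStats(band, p, band_informativeness(p), 0.0 < p < 1.0)


# ---------------------------------------------------------------------------
# Per-primer statistics

def resolving_power(matrix: BandMatrix, primer: str) -> float:
    """Rp: sum of band informativeness over the primer's bands."""
    return sum(
        band_informativeness(band_frequency(matrix, b))
        for b in matrix.bands_of_primer(primer)
    )


def percent_polymorphism(n_total: int, n_poly: int) -> float:
    """%P = 100 * n_poly / n_total (unrounded)."""
    if n_total <= 0:
        raise ValidationError("n_total must be positive")
    if not 0 <= n_poly <= n_total:
        raise ValidationError(f"need 0 <= n_poly <= n_total, got {n_poly}/{n_total}")
    return 100.0 * n_poly / n_total


def pic(matrix: BandMatrix, primer: str, variant: str = "pattern_diversity") -> float:
    """Polymorphic information content of a primer.

    ``pattern_diversity``: 1 - sum f_i^2 over the distinct multiband
    patterns the primer shows across accessions (f_i = fraction of
    accessions with pattern i).  ``mean_band_heterozygosity``: mean over
    the primer's bands of 2p(1-p).  Both lie in [0, 1).
    """
    if variant not in PIC_VARIANTS:
        raise ValidationError(f"unknown PIC variant: {variant!r}; choose from {PIC_VARIANTS}")
    bands = matrix.bands_of_primer(primer)
    cols = matrix.to_frame()[bands].to_numpy()
    if variant == "pattern_diversity":
        counts = Counter(map(tuple, cols))
        n = matrix.n_accessions
        return 1.0 - sum((c / n) ** 2 for c in counts.values())
    freqs = cols.mean(axis=0)
    return float(np.mean(2.0 * freqs * (1.0 - freqs)))


def emr(n_total: int, n_poly: int) -> float:
    """Effective multiplex ratio: n_poly * (n_poly / n_total), unrounded."""
    if n_total <= 0:
        raise ValidationError("n_total must be positive")
    if not 0 <= n_poly <= n_total:
        raise ValidationError(f"need 0 <= n_poly <= n_total, got {n_poly}/{n_total}")
    return n_poly * (n_poly / n_total)


def marker_index(pic_value: float, emr_value: float) -> float:
    """MI = PIC * EMR."""
    if not 0.0 <= pic_value < 1.0:
        raise ValidationError(f"PIC outside [0, 1): {pic_value}")
    if emr_value < 0:
        raise ValidationError(f"negative EMR: {emr_value}")
    return pic_value * emr_value


def primer_summary(
    matrix: BandMatrix, primer: str, pic_variant: str = "pattern_diversity"
) -> PrimerSummary:
    """All informativeness statistics of one primer (unrounded)."""
    bands = matrix.bands_of_primer(primer)
    stats = [band_stats(matrix, b) for b in bands]
    n_total = len(bands)
    n_poly = sum(s.is_polymorphic for s in stats)
    pic_value = pic(matrix, primer, pic_variant)
    emr_value = emr(n_total, n_poly)
    return PrimerSummary(
        primer=primer,
        n_total=n_total,
        n_mono=n_total - n_poly,
        n_poly=n_poly,
        pct_poly=percent_polymorphism(n_total, n_poly),
        pic=pic_value,
        rp=resolving_power(matrix, primer),
        emr=emr_value,
        mi=marker_index(pic_value, emr_value),
    )


@dataclass
class OverallSummary:
    """Column totals and unweighted means across primers.

    ``mean_pct_poly`` averages the *rounded* per-primer integer
    percentages, matching how such tables are conventionally printed;
    ``overall_pct_poly`` is the pooled 100 * sum(PA) / sum(TNA).
    """

    total_bands: int
    total_mono: int
    total_poly: int
    overall_pct_poly: float
    mean_poly: float
    mean_pct_poly: float
    mean_pic: float
    mean_rp: float
    mean_emr: float
    mean_mi: float


def overall_summary(summaries: Sequence[PrimerSummary]) -> OverallSummary:
    if not summaries:
        raise ValidationError("no primer summaries given")
    tna = sum(s.n_total for s in summaries)
    pa = sum(s.n_poly for s in summaries)
    n = len(summaries)
    mean = lambda xs: sum(xs) / n
    return OverallSummary(
        total_bands=tna,
        total_mono=sum(s.n_mono for s in summaries),
        total_poly=pa,
        overall_pct_poly=percent_polymorphism(tna, pa),
        mean_poly=mean([s.n_poly for s in summaries]),
        mean_pct_poly=mean([round_half_up(s.pct_poly) for s in summaries]),
        mean_pic=mean([s.pic for s in summaries]),
        mean_rp=mean([s.rp for s in summaries]),
        mean_emr=mean([s.emr for s in summaries]),
        mean_mi=mean([s.mi for s in summaries]),
    )


def summary_table(
    matrix: BandMatrix, pic_variant: str = "pattern_diversity"
) -> pd.DataFrame:
    """Rendered per-primer table with Total/Mean footer rows.

    Rounding: %P to integer per primer, PIC/RP/EMR/MI to 2 decimals,
    overall %P to 1 decimal, means to 2 decimals.  Raw values are
    available through :func:`primer_summary`.
    """
    summaries = [primer_summary(matrix, p, pic_variant) for p in matrix.primers]
    overall = overall_summary(summaries)
    r2 = lambda x: round_half_up(x, 2)
    rows = [
        {
            "primer": s.primer,
            "TNA": s.n_total,
            "MA": s.n_mono,
            "PA": s.n_poly,
            "pct_P": round_half_up(s.pct_poly),
            "PIC": r2(s.pic),
            "RP": r2(s.rp),
            "EMR": r2(s.emr),
            "MI": r2(s.mi),
        }
        for s in summaries
    ]
    rows.append(
        {
            "primer": "Total",
            "TNA": overall.total_bands,
            "MA": overall.total_mono,
            "PA": overall.total_poly,
            "pct_P": round_half_up(overall.overall_pct_poly, 1),
            "PIC": np.nan, "RP": np.nan, "EMR": np.nan, "MI": np.nan,
        }
    )
    rows.append(
        {
            "primer": "Mean",
            "TNA": np.nan,
            "MA": np.nan,
            "PA": r2(overall.mean_poly),
            "pct_P": r2(overall.mean_pct_poly),
            "PIC": r2(overall.mean_pic),
            "RP": r2(overall.mean_rp),
            "EMR": r2(overall.mean_emr),
            "MI": r2(overall.mean_mi),
        }
    )
    return pd.DataFrame(rows)
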