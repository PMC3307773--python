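"""Peptide-spectrum match (PSM) ingestion and high-confidence filtering.

A TAP-MS purification yields one PSM table per run: every row is a single
MS/MS spectrum matched to a peptide sequence, with the search engine's
identification score, the score margin over the next-best candidate
("delta"), the calibrated relative mass error in ppm and the peptide's
monoisotopic mass in Da.  Downstream quantification only trusts PSMs that
clear all four thresholds of the high-confidence filter (score >= 20,
delta >= 5, |error| <= 5 ppm, mass within 400-6000 Da by default).
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: Default column names of the tab-separated PSM dialect.  Keys are the
#: logical field names, values the header names expected in the file.
DEFAULT_DIALECT: Mapping[str, str] = {
    "purification": "purification",
    "accession": "accession",
    "peptide": "peptide",
    "score": "score",
    "delta": "delta",
    "error_ppm": "error_ppm",
    "peptide_mass": "peptide_mass",
}

#: Separator for multi-mapped accessions within one table cell.
ACCESSION_SEP = ";"


class PSMTableError(ValueError):
    """Raised when a PSM table cannot be interpreted (e.g. missing column)."""


@dataclass(frozen=True)
class PSM:
    """One peptide-spectrum match.

    Parameters
    ----------
    purification_id : str
        Identifier of the purification run the spectrum came from.
    protein_ids : frozenset of str
        Accessions of every protein the peptide maps to (non-empty).
    peptide_sequence : str
        Upper-case peptide sequence over the 20 standard amino acids.
    score : float
        Search-engine identification score (dimensionless).
    delta_score : float
        Score margin over the next-best candidate for the spectrum.
    mass_error : float
        Calibrated relative mass error in ppm (signed).
    peptide_mass : float
        Monoisotopic peptide mass in Da (> 0).
    """

    purification_id: str
    protein_ids: frozenset
    peptide_sequence: str
    score: float
    delta_score: float
    mass_error: float
    peptide_mass: float

    def __post_init__(self) -> None:
        if not self.protein_ids:
            raise ValueError("PSM requires at least one protein accession")
        if not self.peptide_sequence:
            raise ValueError("PSM peptide sequence must be non-empty")
        bad = set(self.peptide_sequence) - AMINO_ACIDS
        if bad:
            raise ValueError(
                f"peptide {self.peptide_sequence!r} contains invalid residues "
                f"{sorted(bad)}"
            )
        if not self.peptide_mass > 0:
            raise ValueError("peptide_mass must be > 0")
        object.__setattr__(self, "protein_ids", frozenset(self.protein_ids))
        for name in ("score", "delta_score", "mass_error", "peptide_mass"):
            object.__setattr__(self, name, float(getattr(self, name)))


@dataclass(frozen=True)
class FilterCriteria:
    """Thresholds of the high-confidence PSM filter (all bounds inclusive)."""

    min_score: float = 20.0
    min_delta: float = 5.0
    max_abs_error: float = 5.0
    mass_window: tuple = (400.0, 6000.0)

    def __post_init__(self) -> None:
        lo, hi = self.mass_window
        if not lo < hi:
            raise ValueError("mass_window lower bound must be < upper bound")
        if min(self.min_score, self.min_delta, self.max_abs_error, lo) < 0:
            raise ValueError("filter thresholds must be >= 0")

    def passes(self, psm: PSM) -> bool:
        lo, hi = self.mass_window
        return (
            psm.score >= self.min_score
            and psm.delta_score >= self.min_delta
            and abs(psm.mass_error) <= self.max_abs_error
            and lo <= psm.peptide_mass <= hi
        )


@dataclass(frozen=True)
class ParseIssue:
    """A row of a PSM table that could not be parsed."""

    row_number: int  # 1-based data-row number (header excluded)
    message: str


@dataclass
class PSMReadResult:
    """PSMs read from a table plus the rows that failed to parse."""

    psms: list = field(default_factory=list)
    issues: list = field(default_factory=list)

    def __iter__(self):
        return iter(self.psms)

    def __len__(self) -> int:
        return len(self.psms)


def _resolve_columns(header: Sequence[str], dialect: Mapping[str, str]) -> Mapping[str, int]:
    positions = {}
    for logical, column in dialect.items():
        if column not in header:
            raise PSMTableError(
                f"mandatory column {column!r} (field {logical!r}) missing from "
                f"PSM table header {list(header)}"
            )
        positions[logical] = header.index(column)
    return positions


def read_psm_table(path, dialect: Mapping[str, str] | None = None) -> PSMReadResult:
    """Read a tab-separated PSM table.

    Rows whose numeric fields fail to parse, or whose PSM violates a type
    invariant, are collected as :class:`ParseIssue` entries rather than
    silently dropped.  An empty file yields an empty result and a warning.
    """
    dialect = dict(DEFAULT_DIALECT if dialect is None else dialect)
    path = Path(path)
    result = PSMReadResult()
    with path.open(newline="", encoding="utf-8") as handle:
        reader = csv.reader(handle, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            warnings.warn(f"PSM table {path} is empty", stacklevel=2)
            return result
        cols = _resolve_columns(header, dialect)
        for row_number, row in enumerate(reader, start=1):
            if not any(cell.strip() for cell in row):
                continue
            try:
                accessions = frozenset(
                    acc.strip()
                    for acc in row[cols["accession"]].split(ACCESSION_SEP)
                    if acc.strip()
                )
                psm = PSM(
                    purification_id=row[cols["purification"]].strip(),
                    protein_ids=accessions,
                    peptide_sequence=row[cols["peptide"]].strip().upper(),
                    score=float(row[cols["score"]]),
                    delta_score=float(row[cols["delta"]]),
                    mass_error=float(row[cols["error_ppm"]]),
                    peptide_mass=float(row[cols["peptide_mass"]]),
                )
            except (ValueError, IndexError) as exc:
                result.issues.append(ParseIssue(row_number, str(exc)))
            else:
                result.psms.append(psm)
    return result


def write_psm_table(psms: Iterable[PSM], path, dialect: Mapping[str, str] | None = None) -> None:
    """Write PSMs as a tab-separated table in the given column dialect."""
    dialect = dict(DEFAULT_DIALECT if dialect is None else dialect)
    order = ["purification", "accession", "peptide", "score", "delta", "error_ppm", "peptide_mass"]
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow([dialect[k] for k in order])
        for psm in psms:
            writer.writerow(
                [
                    psm.purification_id,
                    ACCESSION_SEP.join(sorted(psm.protein_ids)),
                    psm.peptide_sequence,
                    repr(psm.score),
                    repr(psm.delta_score),
                    repr(psm.mass_error),
                    repr(psm.peptide_mass),
                ]
            )


def filter_high_confidence(psms: Iterable[PSM], criteria: FilterCriteria | None = None) -> list:
    """Return exactly the PSMs passing all four thresholds, in input order."""
    criteria = criteria or FilterCriteria()
    return [psm for psm in psms if criteria.passes(psm)]


def distinct_observed_peptides(psms: Iterable[PSM], protein: str) -> int:
    """Number of unique peptide sequences mapping to *protein*.

    Re-sequenced peptides (the same sequence observed in several spectra)
    count once; a protein with no mapped PSM yields 0.  The caller scopes
    the PSM collection (typically one purification, already filtered).
    """
    return len({p.peptide_sequence for p in psms if protein in p.protein_ids})
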