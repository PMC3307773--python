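"""In-silico tryptic digestion and the emPAI abundance index.

The exponentially modified Protein Abundance Index estimates relative
protein abundance from identification coverage alone:

    emPAI = 10 ** (N_observed / N_observable) - 1

where ``N_observed`` is the number of distinct high-confidence peptides
sequenced for the protein and ``N_observable`` the number of unique
tryptic peptides of the protein whose monoisotopic mass falls in the
instrument-accessible window (400-6000 Da here).  Digestion follows the
Keil rule: trypsin cuts C-terminal to K or R unless the next residue is
proline.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from pyteomics import mass as _pyteomics_mass

from .identifications import AMINO_ACIDS

#: Monoisotopic mass of water, added once per peptide (N- and C-termini).
WATER_MONO = 18.010565

#: Default instrument-accessible peptide mass window in Da (closed).
DEFAULT_MASS_WINDOW = (400.0, 6000.0)

_KEIL_SITE = re.compile(r"(?<=[KR])(?!P)")


class InvalidResidueError(ValueError):
    """A sequence contains a residue outside the 20-letter alphabet."""


class UndefinedAbundanceError(ValueError):
    """emPAI is undefined: the protein has no observable peptide."""


def _check_sequence(sequence: str, what: str = "sequence") -> None:
    if not sequence:
        raise InvalidResidueError(f"empty {what} is invalid")
    for position, residue in enumerate(sequence, start=1):
        if residue not in AMINO_ACIDS:
            raise InvalidResidueError(
                f"invalid residue {residue!r} at position {position} in {what}"
            )


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence with its accession and free-text description."""

    accession: str
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        _check_sequence(self.sequence, f"protein {self.accession}")


@dataclass(frozen=True)
class DigestPolicy:
    """How the in-silico digestion mirrors the bench trypsin digestion.

    ``missed_cleavages`` extends the fully cleaved fragment set with all
    concatenations of up to that many adjacent fragments; the default 0
    models ideal digestion, which is also what the observable-peptide
    count of emPAI assumes.
    """

    missed_cleavages: int = 0
    mass_kind: str = "monoisotopic"

    def __post_init__(self) -> None:
        if not 0 <= self.missed_cleavages <= 5:
            raise ValueError("missed_cleavages must be in [0, 5]")
        if self.mass_kind != "monoisotopic":
            raise ValueError("only monoisotopic masses are supported")


@dataclass(frozen=True)
class ObservablePeptideSet:
    """Unique digest peptides of one protein inside the mass window."""

    accession: str
    peptides: frozenset

    @property
    def n_observable(self) -> int:
        return len(self.peptides)


def read_fasta(path, on_invalid: str = "error") -> dict:
    """Read protein records from FASTA, keyed by accession (first header token).

    ``on_invalid`` controls records with residues outside the 20-letter
    alphabet (B/Z/X/U...): ``"error"`` raises, ``"skip"`` drops the record
    with a warning.
    """
    if on_invalid not in {"error", "skip"}:
        raise ValueError("on_invalid must be 'error' or 'skip'")
    records = {}
    for rec in SeqIO.parse(str(Path(path)), "fasta"):
        try:
            protein = ProteinRecord(rec.id, str(rec.seq).upper(), rec.description)
        except InvalidResidueError:
            if on_invalid == "error":
                raise
            warnings.warn(f"skipping FASTA record {rec.id}: non-standard residues", stacklevel=2)
            continue
        records[protein.accession] = protein
    return records


def write_fasta(records: Iterable[ProteinRecord], path) -> None:
    with Path(path).open("w", encoding="utf-8") as handle:
        for rec in records:
            header = rec.accession if not rec.description else rec.description
            if not header.startswith(rec.accession):
                header = f"{rec.accession} {header}"
            handle.write(f">{header}\n")
            for i in range(0, len(rec.sequence), 60):
                handle.write(rec.sequence[i : i + 60] + "\n")


def cleavage_fragments(sequence: str) -> list:
    """Maximal fragments between Keil-rule cut sites, in N->C order."""
    return [frag for frag in _KEIL_SITE.split(sequence) if frag]


def digest(protein: ProteinRecord | str, policy: DigestPolicy | None = None) -> list:
    """Tryptic peptides of a protein, in N-terminal to C-terminal order.

    With ``missed_cleavages = 0`` these are the maximal fragments between
    Keil-rule cut sites (their concatenation is the input sequence); with
    ``k > 0`` all runs of at most ``k + 1`` adjacent fragments are added,
    ordered by start position then length.
    """
    policy = policy or DigestPolicy()
    sequence = protein.sequence if isinstance(protein, ProteinRecord) else protein
    _check_sequence(sequence)
    fragments = cleavage_fragments(sequence)
    if policy.missed_cleavages == 0:
        return fragments
    peptides = []
    for start in range(len(fragments)):
        stop_max = min(len(fragments), start + policy.missed_cleavages + 1)
        for stop in range(start + 1, stop_max + 1):
            peptides.append("".join(fragments[start:stop]))
    return peptides


def peptide_monoisotopic_mass(peptide: str) -> float:
    """Neutral monoisotopic peptide mass: residue masses plus one water."""
    _check_sequence(peptide, "peptide")
    return float(_pyteomics_mass.fast_mass(peptide))


def count_observable(
    protein: ProteinRecord,
    policy: DigestPolicy | None = None,
    window: tuple = DEFAULT_MASS_WINDOW,
) -> ObservablePeptideSet:
    """Unique digest peptides whose monoisotopic mass lies in the closed window."""
    lo, hi = window
    peptides = frozenset(
        pep
        for pep in set(digest(protein, policy))
        if lo <= peptide_monoisotopic_mass(pep) <= hi
    )
    return ObservablePeptideSet(protein.accession, peptides)


def empai(n_obs: int, n_observable: int, clamp: bool = True) -> float:
    """emPAI = 10**(n_obs/n_observable) - 1.

    ``n_obs > n_observable`` can occur under all-mapped peptide crediting
    or when missed-cleavage peptides are observed; the ratio is then
    clamped at 1 (emPAI <= 9) with a warning unless ``clamp`` is False.
    """
    if n_observable < 1:
        raise UndefinedAbundanceError(
            "protein has no observable peptide; emPAI is undefined"
        )
    if n_obs < 0:
        raise ValueError("n_obs must be >= 0")
    ratio = n_obs / n_observable
    if ratio > 1:
        if not clamp:
            raise ValueError(f"n_obs {n_obs} exceeds n_observable {n_observable}")
        warnings.warn(
            f"n_obs {n_obs} exceeds n_observable {n_observable}; clamping ratio at 1",
            stacklevel=2,
        )
        ratio = 1.0
    return 10.0 ** ratio - 1.0
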