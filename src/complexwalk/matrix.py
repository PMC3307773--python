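"""Bait x prey co-purification matrices of emPAI values.

The central object of the pipeline: one row per protein, one column per
purification run (eight tagged baits plus one untagged control in the
packaged reference matrix), each cell holding the protein's emPAI in
that purification.  Zero means "no high-confidence peptide", which the
detection queries read as not detected.  Proteins with signal in the
untagged control column are flagged as background (contaminants such as
actin); flags annotate rows, they never remove them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .digestion import (
    DEFAULT_MASS_WINDOW,
    DigestPolicy,
    ProteinRecord,
    count_observable,
    empai,
)
from .identifications import (
    PSM,
    FilterCriteria,
    distinct_observed_peptides,
    filter_high_confidence,
)

#: Column prefix marking per-protein annotation columns in matrix TSV files.
ANNOTATION_PREFIX = "ann_"


class MatrixError(ValueError):
    """Raised for unknown labels, missing columns or inconsistent inputs."""


@dataclass(frozen=True)
class PurificationRun:
    """One purification: a bait accession (None for the untagged control)
    and the PSMs identified in its preparation."""

    purification_id: str
    bait_accession: str | None
    psms: tuple = ()

    @property
    def is_control(self) -> bool:
        return self.bait_accession is None

    def __post_init__(self) -> None:
        object.__setattr__(self, "psms", tuple(self.psms))


@dataclass
class CopurificationMatrix:
    """emPAI values per (protein, purification), with annotations and flags.

    ``values`` is a pandas DataFrame indexed by protein accession with one
    column per purification id.  ``annotations`` carries static per-protein
    fields (alternative names, mRNA index); the ``alternative_names``
    annotation feeds the name-resolution used by every lookup, so queries
    may use either a row accession or any of its alternative names.
    """

    values: pd.DataFrame
    annotations: pd.DataFrame = field(default_factory=pd.DataFrame)
    control_id: str | None = None
    background: set = field(default_factory=set)

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates or self.values.columns.has_duplicates:
            raise MatrixError("row and column labels must be unique")
        if (self.values.to_numpy() < 0).any():
            raise MatrixError("emPAI values must be >= 0")
        self._name_map = self._build_name_map()

    # -- name resolution ------------------------------------------------

    def _build_name_map(self) -> dict:
        name_map = {}
        for accession in self.values.index:
            name_map.setdefault(accession.casefold(), accession)
        if "alternative_names" in self.annotations.columns:
            for accession, names in self.annotations["alternative_names"].items():
                if not isinstance(names, str):
                    continue
                for name in names.split(","):
                    name = name.strip().casefold()
                    if name:
                        name_map.setdefault(name, accession)
        return name_map

    def resolve(self, protein: str) -> str:
        """Map a protein name (accession or alternative name) to its row."""
        try:
            return self._name_map[protein.casefold()]
        except KeyError:
            raise MatrixError(f"unknown protein {protein!r}") from None

    # -- basic queries ---------------------------------------------------

    @property
    def proteins(self) -> list:
        return list(self.values.index)

    @property
    def purifications(self) -> list:
        return list(self.values.columns)

    def noncontrol_purifications(self) -> list:
        return [p for p in self.values.columns if p != self.control_id]

    def value(self, protein: str, purification: str) -> float:
        if purification not in self.values.columns:
            raise MatrixError(f"unknown purification {purification!r}")
        return float(self.values.at[self.resolve(protein), purification])

    def detected(self, protein: str, purification: str) -> bool:
        """True iff the protein has emPAI > 0 in the purification."""
        return self.value(protein, purification) > 0

    # -- serialization ---------------------------------------------------

    def to_tsv(self, path) -> None:
        """Write the matrix in the TSV dialect read by :func:`matrix_from_tsv`.

        Values are written with ``repr`` (shortest round-tripping decimal),
        never re-rounded, so write -> read -> write is byte-stable.
        """
        out = self.values.copy()
        out = out.map(lambda v: repr(float(v)) if v != int(v) else repr(int(v)))
        for column in self.annotations.columns:
            out[ANNOTATION_PREFIX + column] = self.annotations[column]
        out.index.name = "protein"
        out.to_csv(Path(path), sep="\t")

    def to_frame(self) -> pd.DataFrame:
        return self.values.copy()


def matrix_from_tsv(path, control_id: str | None = None) -> CopurificationMatrix:
    """Read a matrix TSV (first column protein, ``ann_``-prefixed annotations)."""
    frame = pd.read_csv(Path(path), sep="\t", index_col=0, dtype=str)
    ann_cols = [c for c in frame.columns if c.startswith(ANNOTATION_PREFIX)]
    annotations = frame[ann_cols].rename(
        columns={c: c[len(ANNOTATION_PREFIX):] for c in ann_cols}
    )
    values = frame.drop(columns=ann_cols).astype(float)
    if control_id is not None and control_id not in values.columns:
        raise MatrixError(f"control column {control_id!r} not present")
    return CopurificationMatrix(values=values, annotations=annotations, control_id=control_id)


def load_table1_fixture() -> CopurificationMatrix:
    """The packaged reference matrix: 38 proteins x 9 purifications.

    Columns are the untagged control ("TAP") and the eight bait
    purifications INI1, SS18, SS18SSX1, BCL7A, BCL7C, DPF2, BRD9 and
    PHF10; values are emPAI as printed in the source study.
    """
    with resources.as_file(
        resources.files("complexwalk.fixtures") / "table1.tsv"
    ) as path:
        return matrix_from_tsv(path, control_id="TAP")


def build_matrix(
    runs: Sequence[PurificationRun],
    db: Mapping[str, ProteinRecord] | Iterable[ProteinRecord],
    criteria: FilterCriteria | None = None,
    policy: DigestPolicy | None = None,
    window: tuple = DEFAULT_MASS_WINDOW,
) -> CopurificationMatrix:
    """Compose filter -> distinct-peptide count -> emPAI into a matrix.

    ``value(p, r)`` is the emPAI of protein ``p`` computed from its
    distinct high-confidence peptides in run ``r`` and its observable
    tryptic peptide count from the sequence database ``db``.  Proteins
    with no retained observation anywhere are omitted.  A protein that is
    observed but has zero observable peptides is a model inconsistency
    and raises.
    """
    if not runs:
        raise MatrixError("at least one purification run is required")
    criteria = criteria or FilterCriteria()
    policy = policy or DigestPolicy()
    if not isinstance(db, Mapping):
        db = {rec.accession: rec for rec in db}

    retained = {run.purification_id: filter_high_confidence(run.psms, criteria) for run in runs}
    observed_proteins = sorted(
        {acc for psms in retained.values() for psm in psms for acc in psm.protein_ids}
    )
    missing = [acc for acc in observed_proteins if acc not in db]
    if missing:
        raise MatrixError(f"sequence database lacks observed accessions: {missing}")

    n_observable = {}
    for acc in observed_proteins:
        n = count_observable(db[acc], policy, window).n_observable
        if n == 0:
            raise MatrixError(
                f"protein {acc} has observed peptides but no observable tryptic "
                f"peptide in the {window} Da window"
            )
        n_observable[acc] = n

    columns = {}
    for run in runs:
        psms = retained[run.purification_id]
        columns[run.purification_id] = [
            empai(distinct_observed_peptides(psms, acc), n_observable[acc])
            for acc in observed_proteins
        ]
    values = pd.DataFrame(columns, index=pd.Index(observed_proteins, name="protein"))
    values = values.loc[(values > 0).any(axis=1)]
    control_ids = [run.purification_id for run in runs if run.is_control]
    if len(control_ids) > 1:
        raise MatrixError(f"multiple control runs: {control_ids}")
    return CopurificationMatrix(
        values=values, control_id=control_ids[0] if control_ids else None
    )


def flag_background(matrix: CopurificationMatrix, control_id: str | None = None) -> CopurificationMatrix:
    """Flag proteins with emPAI > 0 in the untagged-control column.

    Returns a new matrix with ``background`` set; rows are never removed.
    """
    control_id = control_id if control_id is not None else matrix.control_id
    if control_id is None or control_id not in matrix.values.columns:
        raise MatrixError(f"control column {control_id!r} not present in matrix")
    flagged = set(matrix.values.index[matrix.values[control_id] > 0])
    return CopurificationMatrix(
        values=matrix.values.copy(),
        annotations=matrix.annotations.copy(),
        control_id=control_id,
        background=flagged,
    )
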