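"""Marker-based BAF/PBAF classification and the co-purification network.

Human SWI/SNF complexes come in two broad classes distinguished by
mutually exclusive marker subunits: BAF-class complexes carry either one
of the ARID1A/ARID1B paralogs, while PBAF-class complexes carry both
ARID2 and polybromo (BAF180).  Given a bait's purification column, the
classifier asks which marker group is credibly present and how lopsided
the marker yields are:

* the BAF group is *present* if any of its markers is detected
  (the paralogs are alternatives within one complex);
* the PBAF group is *present* only if all of its markers are detected
  (a PBAF complex carries both);
* with a single group present the bait gets that label; with both
  present the bait is called one-sided only when the summed marker
  yield of one group exceeds the other by at least ``specificity_ratio``
  (default 50), otherwise "both"; with neither, "unassigned".

The same matrix also yields the bait-prey interaction network (edge
weight = emPAI, mirroring edge thickness in co-purification diagrams),
reciprocal-detection reports and co-purification counts.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd

from .matrix import CopurificationMatrix, MatrixError


@dataclass(frozen=True)
class CatalogEntry:
    """One curated subunit: names, complex class and fly/yeast orthologs."""

    accession: str
    alternative_names: tuple = ()
    complex_class: str = "unclassified"  # Core | BAF | PBAF | unclassified
    fly_ortholog: str = ""
    fly_complex: str = ""
    yeast_swi_snf: str = ""
    yeast_rsc: str = ""

    def __post_init__(self) -> None:
        if self.complex_class not in {"Core", "BAF", "PBAF", "unclassified"}:
            raise ValueError(f"invalid complex class {self.complex_class!r}")


class SubunitCatalog:
    """Curated protein -> {Core, BAF, PBAF} catalog with ortholog columns."""

    def __init__(self, entries: Iterable[CatalogEntry]):
        self._entries = {}
        for entry in entries:
            if entry.accession in self._entries:
                raise ValueError(f"duplicate catalog accession {entry.accession!r}")
            self._entries[entry.accession] = entry

    def __len__(self) -> int:
        return len(self._entries)

    def __iter__(self):
        return iter(self._entries.values())

    def __contains__(self, accession: str) -> bool:
        return accession in self._entries

    def __getitem__(self, accession: str) -> CatalogEntry:
        return self._entries[accession]

    def members(self, complex_class: str) -> list:
        return [e.accession for e in self if e.complex_class == complex_class]


def load_table2_catalog() -> SubunitCatalog:
    """The packaged human SWI/SNF subunit catalog with fly/yeast orthologs."""
    with resources.as_file(
        resources.files("complexwalk.fixtures") / "table2.tsv"
    ) as path, Path(path).open(newline="", encoding="utf-8") as handle:
        reader = csv.DictReader(handle, delimiter="\t")
        entries = []
        for row in reader:
            alt = tuple(
                name.strip()
                for name in (row.get("alternative_names") or "").split(",")
                if name.strip()
            )
            entries.append(
                CatalogEntry(
                    accession=row["human_protein"].strip(),
                    alternative_names=alt,
                    complex_class=(row.get("complex_class") or "").strip() or "unclassified",
                    fly_ortholog=(row.get("fly_ortholog") or "").strip(),
                    fly_complex=(row.get("fly_complex") or "").strip(),
                    yeast_swi_snf=(row.get("yeast_swi_snf") or "").strip(),
                    yeast_rsc=(row.get("yeast_rsc") or "").strip(),
                )
            )
    return SubunitCatalog(entries)


@dataclass(frozen=True)
class MarkerScheme:
    """Marker sets and decision thresholds for BAF/PBAF classification.

    detection_threshold is exclusive (default 0: one high-confidence
    peptide suffices).  ``baf_presence``/``pbaf_presence`` choose whether
    a group counts as present when "any" or "all" of its markers are
    detected.  ``aggregation`` sums marker emPAI per group ("sum",
    pooling mutually exclusive paralogs) or takes the maximum ("max").
    """

    baf_markers: tuple = ("ARID1A", "ARID1B")
    pbaf_markers: tuple = ("ARID2", "BAF180")
    detection_threshold: float = 0.0
    specificity_ratio: float = 50.0
    baf_presence: str = "any"
    pbaf_presence: str = "all"
    aggregation: str = "sum"

    def __post_init__(self) -> None:
        if not self.baf_markers or not self.pbaf_markers:
            raise ValueError("marker sets must be non-empty")
        if set(self.baf_markers) & set(self.pbaf_markers):
            raise ValueError("marker sets must be disjoint")
        for mode in (self.baf_presence, self.pbaf_presence):
            if mode not in {"any", "all"}:
                raise ValueError("presence mode must be 'any' or 'all'")
        if self.aggregation not in {"sum", "max"}:
            raise ValueError("aggregation must be 'sum' or 'max'")
        if self.specificity_ratio < 1:
            raise ValueError("specificity_ratio must be >= 1")


@dataclass(frozen=True)
class ComplexAssignment:
    """Per-bait classification with its marker-yield evidence."""

    bait: str
    label: str  # BAF | PBAF | both | unassigned
    baf_yield: float
    pbaf_yield: float
    baf_present: bool
    pbaf_present: bool
    evidence: Mapping[str, float] = field(default_factory=dict)
    scheme: MarkerScheme = field(default_factory=MarkerScheme)
    note: str = ""

    def __post_init__(self) -> None:
        expected = _decide_label(
            self.baf_yield, self.pbaf_yield, self.baf_present, self.pbaf_present, self.scheme
        )
        if self.label != expected:
            raise ValueError(
                f"label {self.label!r} inconsistent with yields under the scheme "
                f"(expected {expected!r})"
            )


def _decide_label(
    baf_yield: float,
    pbaf_yield: float,
    baf_present: bool,
    pbaf_present: bool,
    scheme: MarkerScheme,
) -> str:
    if not baf_present and not pbaf_present:
        return "unassigned"
    if baf_present and not pbaf_present:
        return "BAF"
    if pbaf_present and not baf_present:
        return "PBAF"
    if pbaf_yield > 0 and baf_yield / pbaf_yield >= scheme.specificity_ratio:
        return "BAF"
    if baf_yield > 0 and pbaf_yield / baf_yield >= scheme.specificity_ratio:
        return "PBAF"
    return "both"


def _marker_values(matrix: CopurificationMatrix, bait: str, markers: Iterable[str]) -> dict:
    if bait not in matrix.values.columns:
        raise MatrixError(f"unknown bait purification {bait!r}")
    values = {}
    for marker in markers:
        try:
            values[marker] = matrix.value(marker, bait)
        except MatrixError:
            values[marker] = 0.0  # absent marker rows contribute 0
    return values


def _aggregate(values: Iterable[float], aggregation: str) -> float:
    values = list(values)
    if not values:
        return 0.0
    return max(values) if aggregation == "max" else sum(values)


def marker_yield(
    matrix: CopurificationMatrix,
    bait: str,
    markers: Iterable[str],
    aggregation: str = "sum",
) -> float:
    """Aggregated emPAI of the marker set in the bait's column."""
    return _aggregate(_marker_values(matrix, bait, markers).values(), aggregation)


def classify_bait(
    matrix: CopurificationMatrix,
    bait: str,
    scheme: MarkerScheme | None = None,
) -> ComplexAssignment:
    """Classify one bait purification as BAF, PBAF, both or unassigned."""
    scheme = scheme or MarkerScheme()
    baf_values = _marker_values(matrix, bait, scheme.baf_markers)
    pbaf_values = _marker_values(matrix, bait, scheme.pbaf_markers)
    thr = scheme.detection_threshold
    presence = {"any": any, "all": all}
    baf_present = presence[scheme.baf_presence](v > thr for v in baf_values.values())
    pbaf_present = presence[scheme.pbaf_presence](v > thr for v in pbaf_values.values())
    baf_yield = _aggregate(baf_values.values(), scheme.aggregation)
    pbaf_yield = _aggregate(pbaf_values.values(), scheme.aggregation)
    label = _decide_label(baf_yield, pbaf_yield, baf_present, pbaf_present, scheme)
    note = ""
    if label == "both" and min(baf_yield, pbaf_yield) > 0:
        lop = max(baf_yield, pbaf_yield) / min(baf_yield, pbaf_yield)
        if lop > 1:
            side = "BAF" if baf_yield > pbaf_yield else "PBAF"
            note = f"mixed evidence; {side} markers {lop:.1f}-fold higher"
    return ComplexAssignment(
        bait=bait,
        label=label,
        baf_yield=baf_yield,
        pbaf_yield=pbaf_yield,
        baf_present=baf_present,
        pbaf_present=pbaf_present,
        evidence={**baf_values, **pbaf_values},
        scheme=scheme,
        note=note,
    )


def classify_all(matrix: CopurificationMatrix, scheme: MarkerScheme | None = None) -> list:
    """Classify every non-control purification column."""
    return [classify_bait(matrix, bait, scheme) for bait in matrix.noncontrol_purifications()]


def build_network(
    matrix: CopurificationMatrix,
    bait_map: Mapping[str, str] | None = None,
    keep_self_edges: bool = False,
) -> nx.DiGraph:
    """Bait -> prey network with emPAI edge weights.

    One edge per nonzero (bait, prey) cell of the non-control columns;
    control detections never become edges.  Bait nodes keep their
    purification id (two purifications of the same protein, e.g. a
    wild-type and a fusion construct, stay distinct); ``bait_map``
    records the accession the bait's fusion protein is reported under as
    a node attribute and suppresses the bait's own row as a self-edge
    unless ``keep_self_edges``.
    """
    baits = matrix.noncontrol_purifications()
    if not baits:
        raise MatrixError("matrix has no non-control purification")
    graph = nx.DiGraph()
    for bait in baits:
        bait_protein = (bait_map or {}).get(bait, bait)
        graph.add_node(bait, bait=True, protein=bait_protein)
        for protein in matrix.proteins:
            weight = matrix.value(protein, bait)
            if weight <= 0:
                continue
            if protein == bait_protein and not keep_self_edges:
                continue
            if not graph.has_node(protein):
                graph.add_node(protein, bait=False)
            graph.add_edge(bait, protein, weight=weight)
    return graph


def write_sif(graph: nx.DiGraph, path, relation: str = "copurifies") -> None:
    """Write the network in simple interaction format (SIF)."""
    with Path(path).open("w", encoding="utf-8") as handle:
        for source, target in sorted(graph.edges):
            handle.write(f"{source}\t{relation}\t{target}\n")
        for node in sorted(n for n in graph.nodes if graph.degree(n) == 0):
            handle.write(f"{node}\n")


def reciprocity_report(
    matrix: CopurificationMatrix,
    bait_map: Mapping[str, str],
) -> pd.DataFrame:
    """Pairwise reciprocal-detection table over the mapped baits.

    ``bait_map`` sends each bait purification id to the accession its
    fusion protein is reported under in the matrix rows.  One row per
    unordered bait pair (A, B) with flags "a_detects_b" (is B's protein
    seen in A's purification?) and the converse; a bait against itself is
    excluded.
    """
    baits = matrix.noncontrol_purifications()
    unmapped = [b for b in baits if b not in bait_map]
    if unmapped:
        raise MatrixError(f"bait purifications without a prey-accession mapping: {unmapped}")
    rows = []
    for i, bait_a in enumerate(baits):
        for bait_b in baits[i + 1 :]:
            rows.append(
                {
                    "bait_a": bait_a,
                    "bait_b": bait_b,
                    "a_detects_b": matrix.detected(bait_map[bait_b], bait_a),
                    "b_detects_a": matrix.detected(bait_map[bait_a], bait_b),
                }
            )
    report = pd.DataFrame(rows, columns=["bait_a", "bait_b", "a_detects_b", "b_detects_a"])
    report["reciprocal"] = report["a_detects_b"] & report["b_detects_a"]
    return report


def copurification_count(
    matrix: CopurificationMatrix,
    protein: str,
    purifications: Iterable[str],
) -> int:
    """Number of the listed purifications in which the protein is detected."""
    return sum(matrix.detected(protein, p) for p in purifications)
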