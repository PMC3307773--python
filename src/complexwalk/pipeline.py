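"""End-to-end orchestration: filter -> emPAI -> matrix -> classify -> network.

The pipeline composes the library stages over a run manifest (one PSM
table per purification plus the sequence database) and writes a
deterministic artifact bundle: matrix TSV, classification JSON/TSV,
GraphML + SIF network, a rendered text report and a run log echoing
every effective threshold for provenance.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import networkx as nx
import yaml

from .digestion import DEFAULT_MASS_WINDOW, DigestPolicy, read_fasta
from .identifications import FilterCriteria, read_psm_table
from .matrix import CopurificationMatrix, PurificationRun, build_matrix, flag_background
from .walk import MarkerScheme, build_network, classify_all, reciprocity_report, write_sif


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    """Paths, thresholds and output options of one pipeline invocation.

    ``runs`` maps purification id -> {"psms": path, "bait": accession or
    None for the untagged control}.  All defaults equal the pipeline's
    pinned analysis parameters (filter 20/5/5 ppm, 400-6000 Da window,
    ideal digestion, default marker scheme).
    """

    runs: Mapping[str, Mapping] = field(default_factory=dict)
    fasta: str | Path | None = None
    outdir: str | Path = "complexwalk_out"
    criteria: FilterCriteria = field(default_factory=FilterCriteria)
    policy: DigestPolicy = field(default_factory=DigestPolicy)
    scheme: MarkerScheme = field(default_factory=MarkerScheme)
    mass_window: tuple = DEFAULT_MASS_WINDOW
    bait_map: Mapping[str, str] | None = None

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = {}
        if "runs" in raw:
            kwargs["runs"] = raw["runs"]
        for key in ("fasta", "outdir", "bait_map"):
            if key in raw:
                kwargs[key] = raw[key]
        if "criteria" in raw:
            crit = dict(raw["criteria"])
            if "mass_window" in crit:
                crit["mass_window"] = tuple(crit["mass_window"])
            kwargs["criteria"] = FilterCriteria(**crit)
        if "policy" in raw:
            kwargs["policy"] = DigestPolicy(**raw["policy"])
        if "scheme" in raw:
            kwargs["scheme"] = load_scheme_mapping(raw["scheme"])
        return cls(**kwargs)


def load_scheme_mapping(raw: Mapping) -> MarkerScheme:
    raw = dict(raw)
    for key in ("baf_markers", "pbaf_markers"):
        if key in raw:
            raw[key] = tuple(raw[key])
    return MarkerScheme(**raw)


@dataclass
class PipelineResult:
    matrix: CopurificationMatrix
    assignments: list
    network: nx.DiGraph
    report_text: str
    paths: dict


def _stage(name: str):
    def decorate(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc

        return wrapper

    return decorate


@_stage("read")
def _read_runs(config: PipelineConfig, log: list) -> list:
    runs = []
    for run_id, spec in config.runs.items():
        path = Path(spec["psms"])
        if not path.exists():
            raise FileNotFoundError(f"PSM table for run {run_id!r} not found: {path}")
        result = read_psm_table(path)
        for issue in result.issues:
            log.append(f"read: run {run_id} row {issue.row_number}: {issue.message}")
        log.append(f"read: run {run_id}: {len(result.psms)} PSMs")
        runs.append(PurificationRun(run_id, spec.get("bait"), tuple(result.psms)))
    if not runs:
        raise ValueError("no runs configured")
    return runs


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute all stages and write the artifact bundle to ``config.outdir``."""
    log: list = []
    c = config.criteria
    log.append(
        "parameters: "
        f"min_score={c.min_score} min_delta={c.min_delta} "
        f"max_abs_error={c.max_abs_error} ppm mass_window={c.mass_window} Da "
        f"missed_cleavages={config.policy.missed_cleavages} "
        f"baf_markers={list(config.scheme.baf_markers)} "
        f"pbaf_markers={list(config.scheme.pbaf_markers)} "
        f"specificity_ratio={config.scheme.specificity_ratio}"
    )
    runs = _read_runs(config, log)

    if config.fasta is None or not Path(config.fasta).exists():
        raise PipelineError(f"stage 'sequences' failed: FASTA not found: {config.fasta}")
    db = read_fasta(config.fasta)
    log.append(f"sequences: {len(db)} protein records")

    matrix = _stage("matrix")(build_matrix)(
        runs, db, config.criteria, config.policy, config.mass_window
    )
    control_ids = [r.purification_id for r in runs if r.is_control]
    if control_ids:
        matrix = _stage("background")(flag_background)(matrix, control_ids[0])
        log.append(f"background: {len(matrix.background)} proteins flagged via {control_ids[0]}")
    log.append(f"matrix: {len(matrix.proteins)} proteins x {len(matrix.purifications)} purifications")

    assignments = _stage("classify")(classify_all)(matrix, config.scheme)
    network = _stage("network")(build_network)(matrix, config.bait_map)
    log.append(f"classify: {len(assignments)} baits; network: {network.number_of_edges()} edges")

    reciprocity = None
    if config.bait_map:
        reciprocity = _stage("reciprocity")(reciprocity_report)(matrix, config.bait_map)
    report_text = render_report(assignments, matrix, reciprocity)

    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "matrix": outdir / "matrix.tsv",
        "classification_json": outdir / "classification.json",
        "classification_tsv": outdir / "classification.tsv",
        "graphml": outdir / "network.graphml",
        "sif": outdir / "network.sif",
        "report": outdir / "report.txt",
        "log": outdir / "run.log",
    }
    matrix.to_tsv(paths["matrix"])
    write_classification_json(assignments, paths["classification_json"])
    write_classification_tsv(assignments, paths["classification_tsv"])
    nx.write_graphml(network, paths["graphml"])
    write_sif(network, paths["sif"])
    paths["report"].write_text(report_text)
    paths["log"].write_text("\n".join(log) + "\n")
    return PipelineResult(matrix, assignments, network, report_text, paths)


def assignments_to_records(assignments) -> list:
    return [
        {
            "bait": a.bait,
            "label": a.label,
            "baf_yield": round(a.baf_yield, 3),
            "pbaf_yield": round(a.pbaf_yield, 3),
            "evidence": {m: round(v, 3) for m, v in a.evidence.items()},
            "note": a.note,
        }
        for a in assignments
    ]


def write_classification_json(assignments, path) -> None:
    Path(path).write_text(
        json.dumps(assignments_to_records(assignments), indent=2, sort_keys=True) + "\n"
    )


def write_classification_tsv(assignments, path) -> None:
    lines = ["bait\tlabel\tbaf_yield\tpbaf_yield\tnote"]
    for a in assignments:
        lines.append(f"{a.bait}\t{a.label}\t{a.baf_yield:.3f}\t{a.pbaf_yield:.3f}\t{a.note}")
    Path(path).write_text("\n".join(lines) + "\n")


def render_report(assignments, matrix: CopurificationMatrix, reciprocity=None) -> str:
    """Deterministic human-readable summary of one pipeline run."""
    lines = []
    baits = matrix.noncontrol_purifications()
    n_controls = len(matrix.purifications) - len(baits)
    lines.append(
        f"Co-purification study: {len(baits)} bait purification(s), "
        f"{n_controls} control(s), {len(matrix.proteins)} proteins."
    )
    if not matrix.proteins or not (matrix.values.to_numpy() > 0).any():
        lines.append("no detections")
        return "\n".join(lines) + "\n"
    lines.append("")
    lines.append("Per-bait complex-class evidence (marker emPAI):")
    for a in assignments:
        evidence = " ".join(f"{m}={v:.3f}" for m, v in a.evidence.items())
        suffix = f"  [{a.note}]" if a.note else ""
        lines.append(
            f"  {a.bait}: {a.label}  (BAF yield {a.baf_yield:.3f}, "
            f"PBAF yield {a.pbaf_yield:.3f}; {evidence}){suffix}"
        )
    if matrix.background:
        lines.append("")
        lines.append(
            "Background-flagged proteins (detected in the untagged control): "
            + ", ".join(sorted(matrix.background))
        )
    if reciprocity is not None and len(reciprocity):
        lines.append("")
        lines.append("Reciprocal detection (bait A detects B / B detects A):")
        for row in reciprocity.itertuples(index=False):
            lines.append(
                f"  {row.bait_a} vs {row.bait_b}: "
                f"{'yes' if row.a_detects_b else 'no'}/{'yes' if row.b_detects_a else 'no'}"
            )
    return "\n".join(lines) + "\n"
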