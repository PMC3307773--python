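"""Synthetic TAP-MS studies with known ground truth.

The generator emulates the design of a complex-walking experiment: a
small proteome containing a shared SWI/SNF-like core, a BAF-specific and
a PBAF-specific subunit set (each with its marker pair), contaminants,
eight bait purifications and one untagged control.  For every run,
protein pull-down intensity is the efficiency-weighted abundance of the
protein in the complexes the bait participates in; each observable
tryptic peptide is then sequenced with probability 1 - exp(-kappa *
intensity), a saturating response that reaches full peptide coverage
(emPAI = 9) for efficiently pulled baits.  Retained PSMs draw their
score/delta/mass-error from above-threshold distributions; an explicit
fraction of decoy PSMs falls strictly below exactly one filter criterion
each, so the high-confidence filter has real work to do.

Everything is driven by one integer seed; a fixed seed reproduces the
study byte-for-byte.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np

from .digestion import (
    DEFAULT_MASS_WINDOW,
    DigestPolicy,
    ProteinRecord,
    cleavage_fragments,
    count_observable,
    peptide_monoisotopic_mass,
    write_fasta,
)
from .identifications import PSM, write_psm_table
from .matrix import PurificationRun
from .walk import MarkerScheme

_ALPHABET = np.array(list("ACDEFGHIKLMNPQRSTVWY"))

#: Sentinel bait value identifying the untagged control run.
CONTROL = None


class SimulationError(ValueError):
    """Raised for invalid simulation configurations."""


@dataclass(frozen=True)
class ComplexModel:
    """One ground-truth complex: named subunits with relative abundances."""

    name: str
    subunits: Mapping[str, float]
    complex_class: str  # "BAF" or "PBAF"

    def __post_init__(self) -> None:
        if self.complex_class not in {"BAF", "PBAF"}:
            raise SimulationError("complex_class must be 'BAF' or 'PBAF'")
        if not self.subunits:
            raise SimulationError("a complex needs at least one subunit")
        if any(a <= 0 for a in self.subunits.values()):
            raise SimulationError("subunit abundances must be > 0")


@dataclass(frozen=True)
class ScoreModel:
    """Distributions of the identification scores attached to PSMs.

    Retained PSMs: score = 20 + Exp(score_scale), delta = 5 + Exp(delta_scale),
    mass error ~ Normal(0, error_sd) truncated to +/-5 ppm.  ``decoy_fraction``
    adds that fraction of extra PSMs, each violating exactly one criterion.
    """

    score_scale: float = 15.0
    delta_scale: float = 5.0
    error_sd: float = 1.5
    decoy_fraction: float = 0.25


@dataclass(frozen=True)
class SimulationConfig:
    """Ground truth and noise model of one simulated TAP-MS study.

    ``baits`` maps each bait accession to its per-complex pull-down
    efficiency in [0, 1]; a bait appearing in the efficiency map of both
    a BAF and a PBAF complex has ground-truth label "both".  ``kappa``
    scales the saturating peptide-observation response; ``kappa=None``
    switches the noise model off entirely (every observable peptide of
    every pulled protein is observed, and no decoys are emitted).
    """

    complexes: tuple = ()
    baits: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    contaminants: Mapping[str, float] = field(default_factory=dict)
    baf_markers: tuple = ()
    pbaf_markers: tuple = ()
    length_range: tuple = (100, 600)
    kappa: float | None = 4.0
    score_model: ScoreModel = field(default_factory=ScoreModel)
    seed: int = 0
    control_id: str = "CTRL"
    max_redraws: int = 100

    def __post_init__(self) -> None:
        lo, hi = self.length_range
        if not (10 <= lo <= hi):
            raise SimulationError("invalid protein length range")
        names = {c.name for c in self.complexes}
        for bait, effs in self.baits.items():
            for cname, eff in effs.items():
                if cname not in names:
                    raise SimulationError(f"bait {bait!r} references unknown complex {cname!r}")
                if not 0 <= eff <= 1:
                    raise SimulationError("pull-down efficiencies must be in [0, 1]")

    def noise_free(self) -> "SimulationConfig":
        """Copy of the config with the observation noise and decoys off."""
        return replace(self, kappa=None)

    def all_subunits(self) -> list:
        seen = {}
        for cplx in self.complexes:
            for acc in cplx.subunits:
                seen[acc] = None
        for acc in self.contaminants:
            seen[acc] = None
        return list(seen)

    def true_label(self, bait: str) -> str:
        classes = {
            cplx.complex_class
            for cplx in self.complexes
            if self.baits.get(bait, {}).get(cplx.name, 0.0) > 0
        }
        if classes == {"BAF"}:
            return "BAF"
        if classes == {"PBAF"}:
            return "PBAF"
        if classes == {"BAF", "PBAF"}:
            return "both"
        return "unassigned"

    def marker_scheme(self, **overrides) -> MarkerScheme:
        """MarkerScheme whose marker sets are this study's simulated markers."""
        return MarkerScheme(
            baf_markers=self.baf_markers, pbaf_markers=self.pbaf_markers, **overrides
        )


def default_config(seed: int = 0) -> SimulationConfig:
    """The packaged study design: 8 baits (5 BAF-specific, 1 PBAF-specific,
    1 core, 1 dual-resident) + 1 untagged control.

    The proteome holds a 7-member shared core (emulating the
    BRG1/BAF155/BAF170/BAF47/BAF57/BAF60/BAF53 backbone), a BAF-specific
    set with its ARID1-like marker pair, a PBAF-specific set with its
    ARID2/polybromo-like marker pair, and an abundant actin-like
    contaminant present in every run including the control.
    """
    core = {f"CORE{i}": 1.0 for i in range(1, 8)}
    baf_specific = {
        "BAFM1": 0.9,   # ARID1A-like marker
        "BAFM2": 0.7,   # ARID1B-like marker
        "SS18L": 1.0,   # SS18-like
        "DPFL": 0.8,    # DPF-like
        "BCL7L1": 0.8,  # BCL7-like
        "BCL7L2": 0.8,  # BCL7 paralog
        "BRD9L": 0.6,   # BRD9-like
        "DUALL": 0.5,   # dual-resident subunit
    }
    pbaf_specific = {
        "PBM1": 0.9,    # ARID2-like marker
        "PBM2": 0.9,    # polybromo-like marker
        "PHF10L": 1.0,  # PHF10-like
        "BRD7L": 0.6,   # BRD7-like
        "DUALL": 0.5,
    }
    complexes = (
        ComplexModel("BAF", {**core, **baf_specific}, "BAF"),
        ComplexModel("PBAF", {**core, **pbaf_specific}, "PBAF"),
    )
    baits = {
        "SS18L": {"BAF": 0.9},
        "DPFL": {"BAF": 0.8},
        "BCL7L1": {"BAF": 0.7},
        "BCL7L2": {"BAF": 0.7},
        "BRD9L": {"BAF": 0.5},
        "PHF10L": {"PBAF": 0.8},
        "CORE4": {"BAF": 0.4, "PBAF": 0.5},   # INI1-like core bait pulls both
        "DUALL": {"BAF": 0.5, "PBAF": 0.5},
    }
    return SimulationConfig(
        complexes=complexes,
        baits=baits,
        contaminants={"ACTL": 2.0},
        baf_markers=("BAFM1", "BAFM2"),
        pbaf_markers=("PBM1", "PBM2"),
        seed=seed,
    )


def _rng_for(config: SimulationConfig, stream: str) -> np.random.Generator:
    # independent, reproducible stream per (seed, purpose)
    return np.random.default_rng([config.seed, zlib.crc32(stream.encode())])


def simulate_proteome(config: SimulationConfig) -> dict:
    """Reproducible random protein records for every subunit and contaminant.

    Each sequence is redrawn (up to ``max_redraws`` times) until it has at
    least one observable tryptic peptide under the default digest policy.
    """
    rng = _rng_for(config, "proteome")
    lo, hi = config.length_range
    records = {}
    for accession in config.all_subunits():
        for _ in range(config.max_redraws):
            length = int(rng.integers(lo, hi + 1))
            sequence = "".join(rng.choice(_ALPHABET, size=length))
            record = ProteinRecord(accession, sequence, f"{accession} synthetic protein")
            if count_observable(record).n_observable >= 1:
                records[accession] = record
                break
        else:
            raise SimulationError(
                f"could not draw a sequence with observable peptides for {accession}"
            )
    return records


def _run_intensities(config: SimulationConfig, bait: str | None) -> dict:
    """Protein -> pull-down intensity for one run (contaminants included)."""
    intensities = dict(config.contaminants)
    if bait is not CONTROL:
        if bait not in config.baits:
            raise SimulationError(f"unknown bait {bait!r}")
        for cplx in config.complexes:
            efficiency = config.baits[bait].get(cplx.name, 0.0)
            if efficiency <= 0:
                continue
            for acc, abundance in cplx.subunits.items():
                intensities[acc] = intensities.get(acc, 0.0) + efficiency * abundance
    return {acc: val for acc, val in intensities.items() if val > 0}


def _tryptic_index(proteome: Mapping[str, ProteinRecord]) -> dict:
    """peptide -> accessions having it as a tryptic fragment (all-mapped
    crediting with tryptic specificity, as a database search would)."""
    index: dict = {}
    for acc, rec in proteome.items():
        for fragment in set(cleavage_fragments(rec.sequence)):
            index.setdefault(fragment, set()).add(acc)
    return index


def simulate_purification(
    config: SimulationConfig,
    proteome: Mapping[str, ProteinRecord],
    bait: str | None,
) -> list:
    """PSMs of one purification run (``bait=None`` for the untagged control)."""
    run_id = config.control_id if bait is CONTROL else bait
    rng = _rng_for(config, f"run:{run_id}")
    sm = config.score_model
    intensities = _run_intensities(config, bait)
    index = _tryptic_index(proteome)
    psms = []
    genuine_peptides = []  # (peptide, protein) pool for decoys
    for accession in sorted(intensities):
        intensity = intensities[accession]
        if config.kappa is None:
            p_obs = 1.0
        else:
            p_obs = 1.0 - np.exp(-config.kappa * intensity)
        peptides = sorted(count_observable(proteome[accession]).peptides)
        genuine_peptides.extend((pep, accession) for pep in peptides)
        for peptide in peptides:
            if rng.random() > p_obs:
                continue
            psms.append(
                PSM(
                    purification_id=run_id,
                    protein_ids=frozenset(index[peptide]),
                    peptide_sequence=peptide,
                    score=20.0 + rng.exponential(sm.score_scale),
                    delta_score=5.0 + rng.exponential(sm.delta_scale),
                    mass_error=float(np.clip(rng.normal(0.0, sm.error_sd), -5.0, 5.0)),
                    peptide_mass=peptide_monoisotopic_mass(peptide),
                )
            )
    if config.kappa is not None and genuine_peptides and sm.decoy_fraction > 0:
        n_decoys = int(round(sm.decoy_fraction * max(len(psms), 1)))
        for _ in range(n_decoys):
            peptide, accession = genuine_peptides[int(rng.integers(len(genuine_peptides)))]
            score = 20.0 + rng.exponential(sm.score_scale)
            delta = 5.0 + rng.exponential(sm.delta_scale)
            error = float(np.clip(rng.normal(0.0, sm.error_sd), -5.0, 5.0))
            failing = ("score", "delta", "error")[int(rng.integers(3))]
            if failing == "score":
                score = float(rng.uniform(1.0, 19.9))
            elif failing == "delta":
                delta = float(rng.uniform(0.0, 4.9))
            else:
                error = float(rng.choice([-1.0, 1.0]) * rng.uniform(5.1, 25.0))
            psms.append(
                PSM(
                    purification_id=run_id,
                    protein_ids=frozenset(index[peptide]),
                    peptide_sequence=peptide,
                    score=score,
                    delta_score=delta,
                    mass_error=error,
                    peptide_mass=peptide_monoisotopic_mass(peptide),
                )
            )
    return psms


@dataclass
class StudyResult:
    """Simulated runs, their proteome and the ground-truth ledger."""

    config: SimulationConfig
    proteome: dict
    runs: list
    truth: dict

    def write(self, outdir) -> dict:
        """Write FASTA, per-run PSM tables and the truth ledger; return paths."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {"fasta": outdir / "proteome.fasta", "truth": outdir / "truth.json"}
        write_fasta(self.proteome.values(), paths["fasta"])
        paths["runs"] = {}
        for run in self.runs:
            path = outdir / f"{run.purification_id}.psms.tsv"
            write_psm_table(run.psms, path)
            paths["runs"][run.purification_id] = path
        paths["truth"].write_text(json.dumps(self.truth, indent=2, sort_keys=True) + "\n")
        return paths


def generate_study(config: SimulationConfig) -> StudyResult:
    """Simulate one full study: one run per bait plus the untagged control.

    The truth ledger records each bait's ground-truth class label, the
    complex membership map and, per run, the proteins expected to be
    detectable (pull-down intensity > 0).
    """
    if not config.baits:
        raise SimulationError("at least one bait is required")
    proteome = simulate_proteome(config)
    runs = []
    expected = {}
    for bait in list(config.baits) + [CONTROL]:
        run_id = config.control_id if bait is CONTROL else bait
        psms = simulate_purification(config, proteome, bait)
        runs.append(PurificationRun(run_id, bait, tuple(psms)))
        expected[run_id] = sorted(_run_intensities(config, bait))
    truth = {
        "labels": {bait: config.true_label(bait) for bait in config.baits},
        "membership": {c.name: sorted(c.subunits) for c in config.complexes},
        "contaminants": sorted(config.contaminants),
        "expected_detection": expected,
        "seed": config.seed,
    }
    return StudyResult(config=config, proteome=proteome, runs=runs, truth=truth)
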