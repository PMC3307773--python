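"""The synthetic TAP-MS study generator and its ground-truth guarantees."""

import numpy as np
import pytest

from complexwalk.digestion import count_observable
from complexwalk.identifications import FilterCriteria, filter_high_confidence
from complexwalk.matrix import build_matrix
from complexwalk.simulate import (
    ComplexModel,
    ScoreModel,
    SimulationConfig,
    SimulationError,
    default_config,
    generate_study,
    simulate_proteome,
    simulate_purification,
)
from complexwalk.walk import classify_all


def tiny_config(seed=0, **overrides):
    """A two-complex study small enough for per-test simulation."""
    complexes = (
        ComplexModel("BAF", {"CORE1": 1.0, "BM1": 0.9, "BM2": 0.8, "BX": 1.0}, "BAF"),
        ComplexModel("PBAF", {"CORE1": 1.0, "PM1": 0.9, "PM2": 0.9, "PX": 1.0}, "PBAF"),
    )
    defaults = dict(
        complexes=complexes,
        baits={"BX": {"BAF": 0.8}, "PX": {"PBAF": 0.8}, "CORE1": {"BAF": 0.5, "PBAF": 0.5}},
        contaminants={"ACT": 1.5},
        baf_markers=("BM1", "BM2"),
        pbaf_markers=("PM1", "PM2"),
        length_range=(100, 300),
        seed=seed,
    )
    defaults.update(overrides)
    return SimulationConfig(**defaults)


class TestProteome:
    def test_deterministic_under_fixed_seed(self, tmp_path):
        from complexwalk.digestion import write_fasta

        a, b = tmp_path / "a.fasta", tmp_path / "b.fasta"
        write_fasta(simulate_proteome(tiny_config(seed=4)).values(), a)
        write_fasta(simulate_proteome(tiny_config(seed=4)).values(), b)
        assert a.read_bytes() == b.read_bytes()
        write_fasta(simulate_proteome(tiny_config(seed=5)).values(), b)
        assert a.read_bytes() != b.read_bytes()

    def test_counts_and_length_range(self):
        config = tiny_config()
        proteome = simulate_proteome(config)
        assert set(proteome) == set(config.all_subunits())
        lo, hi = config.length_range
        assert all(lo <= len(r.sequence) <= hi for r in proteome.values())

    def test_every_record_has_observable_peptides(self):
        for record in simulate_proteome(tiny_config(seed=2)).values():
            assert count_observable(record).n_observable >= 1


class TestPurification:
    def test_bait_in_no_complex_yields_only_filtered_out_decoys(self):
        config = tiny_config(
            baits={"LONER": {}},
            contaminants={},
        )
        proteome = simulate_proteome(config)
        psms = simulate_purification(config, proteome, "LONER")
        assert filter_high_confidence(psms) == []

    def test_noise_free_full_coverage_gives_empai_nine(self, noise_free_study):
        """Pipeline closed form: every pulled protein at full peptide coverage."""
        study = noise_free_study
        m = build_matrix(study.runs, study.proteome)
        for run_id, present in study.truth["expected_detection"].items():
            for protein in present:
                assert m.value(protein, run_id) == pytest.approx(9.0)

    def test_control_run_contains_contaminants_only(self, noisy_study):
        control = [r for r in noisy_study.runs if r.is_control][0]
        contaminants = set(noisy_study.truth["contaminants"])
        observed = {acc for psm in control.psms for acc in psm.protein_ids}
        assert observed <= contaminants

    def test_decoys_each_fail_exactly_one_criterion(self, noisy_study):
        crit = FilterCriteria()
        for run in noisy_study.runs:
            for psm in run.psms:
                failures = sum(
                    [
                        psm.score < crit.min_score,
                        psm.delta_score < crit.min_delta,
                        abs(psm.mass_error) > crit.max_abs_error,
                    ]
                )
                assert failures <= 1

    def test_unknown_bait_errors(self):
        config = tiny_config()
        proteome = simulate_proteome(config)
        with pytest.raises(SimulationError):
            simulate_purification(config, proteome, "NOT_A_BAIT")

    def test_run_determinism(self):
        config = tiny_config(seed=6)
        proteome = simulate_proteome(config)
        assert simulate_purification(config, proteome, "BX") == simulate_purification(
            config, proteome, "BX"
        )


class TestStudy:
    def test_default_design_produces_nine_tables(self):
        study = generate_study(default_config(seed=1).noise_free())
        assert len(study.runs) == 9
        assert sum(run.is_control for run in study.runs) == 1
        labels = study.truth["labels"]
        assert sorted(labels.values()).count("BAF") == 5
        assert sorted(labels.values()).count("PBAF") == 1
        assert sorted(labels.values()).count("both") == 2

    def test_noise_free_classification_recovers_truth_exactly(self, noise_free_study):
        study = noise_free_study
        m = build_matrix(study.runs, study.proteome)
        labels = {a.bait: a.label for a in classify_all(m, study.config.marker_scheme())}
        assert labels == study.truth["labels"]

    def test_empai_rank_tracks_configured_intensity(self):
        """Across replicates, mean emPAI is non-decreasing in pull-down intensity."""
        # spread the configured abundances so the intensity ranks are far apart:
        # BX pulls BAF at 0.8 -> intensities BM2=0.2, BM1=0.48, BX=0.8
        complexes = (
            ComplexModel("BAF", {"CORE1": 1.0, "BM1": 0.6, "BM2": 0.25, "BX": 1.0}, "BAF"),
            ComplexModel("PBAF", {"CORE1": 1.0, "PM1": 0.9, "PM2": 0.9, "PX": 1.0}, "PBAF"),
        )
        totals = {"BM2": [], "BM1": [], "BX": []}
        for seed in range(25):
            cfg = tiny_config(
                seed=seed,
                kappa=1.5,
                complexes=complexes,
                score_model=ScoreModel(decoy_fraction=0.0),
            )
            proteome = simulate_proteome(cfg)
            m = build_matrix([__import__("complexwalk").PurificationRun(
                "BX", "BX", tuple(simulate_purification(cfg, proteome, "BX")))], proteome)
            for acc in totals:
                totals[acc].append(m.value(acc, "BX") if acc in m.proteins else 0.0)
        means = {acc: np.mean(vals) for acc, vals in totals.items()}
        assert means["BM2"] <= means["BM1"] <= means["BX"]

    def test_study_write_round_trips_psms(self, tmp_path, noisy_study):
        from complexwalk.identifications import read_psm_table

        paths = noisy_study.write(tmp_path / "study")
        run = noisy_study.runs[0]
        reloaded = read_psm_table(paths["runs"][run.purification_id])
        assert tuple(reloaded.psms) == run.psms

    def test_truth_ledger_is_json_serializable(self, noisy_study):
        import json

        json.dumps(noisy_study.truth)


class TestConfigValidation:
    def test_efficiency_out_of_range(self):
        with pytest.raises(SimulationError):
            tiny_config(baits={"BX": {"BAF": 1.5}})

    def test_unknown_complex_reference(self):
        with pytest.raises(SimulationError):
            tiny_config(baits={"BX": {"NOPE": 0.5}})

    def test_noise_free_copy(self):
        assert tiny_config().noise_free().kappa is None
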