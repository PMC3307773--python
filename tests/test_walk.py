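"""Marker yields, BAF/PBAF classification, network and reciprocity."""

import numpy as np
import pandas as pd
import pytest

from complexwalk.matrix import CopurificationMatrix, MatrixError
from complexwalk.walk import (
    ComplexAssignment,
    MarkerScheme,
    build_network,
    classify_all,
    classify_bait,
    copurification_count,
    marker_yield,
    reciprocity_report,
    write_sif,
)

#: Purification id -> the accession its fusion protein is reported under.
BAIT_MAP = {
    "INI1": "BAF47",
    "SS18": "SS18",
    "SS18SSX1": "SS18",
    "BCL7A": "BCL7A",
    "BCL7C": "BCL7C",
    "DPF2": "BAF45D",
    "BRD9": "BRD9",
    "PHF10": "BAF45A",
}


class TestMarkerYield:
    def test_pbaf_yield_of_phf10(self, table1):
        assert marker_yield(table1, "PHF10", ("ARID2", "BAF180")) == pytest.approx(
            0.884 + 1.769
        )

    def test_baf_yield_of_phf10(self, table1):
        assert marker_yield(table1, "PHF10", ("ARID1A", "ARID1B")) == pytest.approx(0.027)

    def test_empty_marker_set_yields_zero(self, table1):
        assert marker_yield(table1, "PHF10", ()) == 0.0

    def test_absent_marker_rows_contribute_zero(self, table1):
        assert marker_yield(table1, "PHF10", ("ARID2", "NOT_IN_MATRIX")) == pytest.approx(0.884)

    def test_unknown_bait_errors(self, table1):
        with pytest.raises(MatrixError):
            marker_yield(table1, "NOT_A_BAIT", ("ARID2",))

    def test_max_aggregation(self, table1):
        assert marker_yield(table1, "PHF10", ("ARID2", "BAF180"), aggregation="max") == 1.769


class TestClassification:
    def test_reference_matrix_reproduces_reported_labels(self, table1):
        expected = {
            "SS18": "BAF",
            "SS18SSX1": "BAF",
            "DPF2": "BAF",
            "BCL7A": "BAF",
            "BRD9": "BAF",
            "PHF10": "PBAF",
            "INI1": "both",
        }
        labels = {a.bait: a.label for a in classify_all(table1)}
        for bait, label in expected.items():
            assert labels[bait] == label, bait

    def test_bcl7c_reported_as_mixed_with_evidence(self, table1):
        """BCL7C's column carries both marker groups; the call stays 'both'
        with the BAF-leaning evidence annotated rather than forced."""
        a = classify_bait(table1, "BCL7C")
        assert a.label == "both"
        assert a.baf_yield == pytest.approx(1.766 + 0.638)
        assert a.pbaf_yield == pytest.approx(0.122 + 0.248)
        assert "BAF markers" in a.note

    def test_phf10_one_sided_by_specificity_ratio(self, table1):
        a = classify_bait(table1, "PHF10")
        assert a.label == "PBAF"
        assert a.baf_yield == pytest.approx(0.027)
        assert a.pbaf_yield == pytest.approx(2.653)
        assert a.pbaf_yield / a.baf_yield >= a.scheme.specificity_ratio

    def test_all_zero_column_unassigned(self, table1):
        a = classify_bait(table1, "TAP")  # untagged control column has no markers
        assert a.label == "unassigned"

    def test_evidence_carries_per_marker_values(self, table1):
        a = classify_bait(table1, "INI1")
        assert a.evidence == pytest.approx(
            {"ARID1A": 0.027, "ARID1B": 0.0, "ARID2": 0.122, "BAF180": 0.457}
        )

    def test_raising_threshold_never_assigns_the_unassigned(self, table1):
        for threshold in (0.0, 0.05, 0.5, 2.0, 20.0):
            scheme = MarkerScheme(detection_threshold=threshold)
            base = {a.bait: a.label for a in classify_all(table1, scheme)}
            higher = {
                a.bait: a.label
                for a in classify_all(table1, MarkerScheme(detection_threshold=threshold + 1))
            }
            for bait, label in base.items():
                if label == "unassigned":
                    assert higher[bait] == "unassigned"

    def test_inconsistent_assignment_rejected(self):
        with pytest.raises(ValueError, match="inconsistent"):
            ComplexAssignment(
                bait="X", label="PBAF", baf_yield=5.0, pbaf_yield=0.0,
                baf_present=True, pbaf_present=False,
            )

    def test_marker_scheme_validation(self):
        with pytest.raises(ValueError):
            MarkerScheme(baf_markers=("A",), pbaf_markers=("A", "B"))
        with pytest.raises(ValueError):
            MarkerScheme(baf_markers=())


class TestNetwork:
    def test_edge_set_equals_nonzero_cells(self, table1):
        """Counting oracle: one edge per nonzero non-control cell (minus
        the bait's own row where the bait is itself a matrix row)."""
        graph = build_network(table1, BAIT_MAP)
        expected = 0
        for bait in table1.noncontrol_purifications():
            for protein in table1.proteins:
                if table1.value(protein, bait) > 0 and protein != BAIT_MAP[bait]:
                    expected += 1
        assert graph.number_of_edges() == expected

    def test_ss18_baf47_edge_weight(self, table1):
        graph = build_network(table1, BAIT_MAP)
        assert graph.edges["SS18", "BAF47"]["weight"] == pytest.approx(5.449)

    def test_never_detected_protein_is_absent(self, table1):
        graph = build_network(table1, BAIT_MAP)
        assert "BAF53B" not in graph.nodes

    def test_control_detections_make_no_edges(self, table1):
        graph = build_network(table1, BAIT_MAP)
        assert "TAP" not in graph.nodes
        # SRRM2/MYBBP1A appear nowhere outside annotation: no node
        assert "SRRM2" not in graph.nodes

    def test_single_bait_synthetic_counting(self):
        values = pd.DataFrame({"b": [1.2, 0.0, 3.3]}, index=["X", "Y", "Z"])
        m = CopurificationMatrix(values=values)
        graph = build_network(m)
        assert graph.number_of_edges() == 2
        assert set(graph.successors("b")) == {"X", "Z"}

    def test_self_edges_dropped_by_default(self, table1):
        dropped = build_network(table1, BAIT_MAP)
        kept = build_network(table1, BAIT_MAP, keep_self_edges=True)
        assert not any(u == v for u, v in dropped.edges)
        assert ("SS18", "SS18") in kept.edges  # bait at full coverage

    def test_sif_writer(self, tmp_path, table1):
        graph = build_network(table1, BAIT_MAP)
        path = tmp_path / "net.sif"
        write_sif(graph, path)
        lines = path.read_text().splitlines()
        assert f"SS18\tcopurifies\tBAF47" in lines
        assert len([l for l in lines if "\t" in l]) == graph.number_of_edges()


class TestReciprocity:
    def test_ini1_vs_ss18_is_one_way(self, table1):
        report = reciprocity_report(table1, BAIT_MAP)
        row = report[(report.bait_a == "INI1") & (report.bait_b == "SS18")].iloc[0]
        assert not row.a_detects_b and row.b_detects_a
        assert not row.reciprocal

    def test_ini1_vs_phf10_is_reciprocal(self, table1):
        report = reciprocity_report(table1, BAIT_MAP)
        row = report[(report.bait_a == "INI1") & (report.bait_b == "PHF10")].iloc[0]
        assert row.a_detects_b and row.b_detects_a

    def test_self_pairs_excluded_and_count(self, table1):
        report = reciprocity_report(table1, BAIT_MAP)
        assert not (report.bait_a == report.bait_b).any()
        assert len(report) == 8 * 7 // 2

    def test_unmapped_bait_errors(self, table1):
        with pytest.raises(MatrixError, match="BRD9"):
            reciprocity_report(table1, {k: v for k, v in BAIT_MAP.items() if k != "BRD9"})


class TestCopurificationCount:
    def test_gltscr1_in_four_of_five_baf_purifications(self, table1):
        baf_runs = {"SS18", "SS18SSX1", "BCL7A", "BCL7C", "DPF2"}
        assert copurification_count(table1, "GLTSCR1", baf_runs) == 4

    def test_empty_purification_set(self, table1):
        assert copurification_count(table1, "GLTSCR1", set()) == 0

    def test_baf47_detected_in_all_seven_non_ini1_baits(self, table1):
        runs = [p for p in table1.noncontrol_purifications() if p != "INI1"]
        assert copurification_count(table1, "BAF47", runs) == 7

    def test_unknown_labels_error(self, table1):
        with pytest.raises(MatrixError):
            copurification_count(table1, "GLTSCR1", {"NOPE"})
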