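"""Exemplar-to-lineage association, bipartite views, module coverage."""

import networkx as nx
import pandas as pd
import pytest

from exemplarnet.affinity import APResult
from exemplarnet.datasets import load_regulator_fixture
from exemplarnet.errors import ValidationError
from exemplarnet.interactome import ProteinNetwork
from exemplarnet.lineage import (
    LineageMap,
    associate_exemplars,
    build_cell_exemplar_bipartite,
    build_regulator_module_multigraph,
    classify_specificity,
    load_regulator_table,
    module_coverage,
)


@pytest.fixture
def toy_lineage_map():
    lmap = load_regulator_fixture()
    lmap.module_assignment = {
        "G1": "M1", "G2": "M1", "G3": "M2", "G4": "M2", "G5": "M3",
    }
    # M1 driven only by an HSC-unique regulator; M2 by one regulator of
    # every cell type; M3 unregulated
    lmap.module_regulation = {("HLF", "M1")} | {
        (sorted(lmap.regulators[ct])[0], "M2") for ct in lmap.cell_types
    }
    return lmap


def result_from_clusters(clusters: dict[str, set[str]]) -> APResult:
    assignment = {g: ex for ex, members in clusters.items() for g in members}
    return APResult(set(clusters), assignment, 0, True, 0.0)


class TestRegulatorTable:
    def test_fixture_has_ten_cell_types(self):
        lmap = load_regulator_fixture()
        assert len(lmap.cell_types) == 10

    def test_monocyte_regulators(self):
        lmap = load_regulator_fixture()
        assert lmap.regulators["Monocytes"] == {"CEBPB", "SFPI1"}

    def test_regulators_shared_across_cell_types_preserved(self):
        lmap = load_regulator_fixture()
        owners = [ct for ct in lmap.cell_types if "SFPI1" in lmap.regulators[ct]]
        assert len(owners) == 5  # B, DC, granulocytes, macrophage, monocytes

    def test_blank_activator_list_is_validation_error(self, tmp_path):
        path = tmp_path / "reg.tsv"
        path.write_text("cell_type\tactivators\nB cells\t\n")
        with pytest.raises(ValidationError):
            load_regulator_table(path)


class TestSpecificityClassification:
    @pytest.mark.parametrize(
        "n_assoc,n_types,expected",
        [(1, 10, "lineage-specific"), (10, 10, "common"), (2, 10, "shared"),
         (9, 10, "shared")],
    )
    def test_boundaries(self, n_assoc, n_types, expected):
        assert classify_specificity(n_assoc, n_types) == expected

    def test_classes_partition_associated_exemplars(self, standard_result,
                                                    standard_dataset):
        table = associate_exemplars(standard_result, standard_dataset["lineage_map"])
        assert set(table["specificity"]) <= {"lineage-specific", "shared", "common"}
        for _, row in table.iterrows():
            assert classify_specificity(row["n_cell_types"], 10) == row["specificity"]


class TestAssociateExemplars:
    def test_single_module_exemplar_is_lineage_specific(self, toy_lineage_map):
        result = result_from_clusters({"G1": {"G1", "G2"}})
        table = associate_exemplars(result, toy_lineage_map)
        row = table.iloc[0]
        assert row["specificity"] == "lineage-specific"
        assert row["cell_types"] == "Hematopoietic stem cells"

    def test_exemplar_in_globally_regulated_module_is_common(self, toy_lineage_map):
        table = associate_exemplars(result_from_clusters({"G3": {"G3", "G4"}}),
                                    toy_lineage_map)
        assert table.iloc[0]["specificity"] == "common"
        assert table.iloc[0]["n_cell_types"] == 10

    def test_unmapped_exemplar_excluded_and_logged(self, toy_lineage_map, caplog):
        clusters = {"G1": {"G1", "G2"}, "X9": {"X9"}}
        with caplog.at_level("WARNING"):
            table = associate_exemplars(result_from_clusters(clusters), toy_lineage_map)
        assert list(table["exemplar"]) == ["G1"]
        assert "X9" in caplog.text

    def test_min_genes_threshold(self, toy_lineage_map):
        # cluster with one gene in the HSC module and one unmapped
        clusters = {"G1": {"G1", "G5"}}
        t1 = associate_exemplars(result_from_clusters(clusters), toy_lineage_map, 1)
        t2 = associate_exemplars(result_from_clusters(clusters), toy_lineage_map, 2)
        assert t1.iloc[0]["specificity"] == "lineage-specific"
        assert t2.iloc[0]["specificity"] == "unassociated"

    def test_planted_classification_recovered(self, standard_result, standard_dataset):
        truth = standard_dataset["truth"]
        lmap = standard_dataset["lineage_map"]
        table = associate_exemplars(standard_result, lmap)
        group_of = {g: gid for gid, m in truth.groups.items() for g in m}
        for _, row in table.iterrows():
            gid = group_of[row["exemplar"]]
            planted = truth.cell_types[gid]
            expected = "common" if len(planted) == 10 else "lineage-specific"
            assert row["specificity"] == expected
            if expected == "lineage-specific":
                assert row["cell_types"] == planted[0]


class TestBipartiteViews:
    def test_single_specific_exemplar_edge(self):
        table = pd.DataFrame([
            {"exemplar": "E1", "genes": "A", "cell_types": "B cells",
             "n_cell_types": 1, "specificity": "lineage-specific"},
        ])
        g = build_cell_exemplar_bipartite(table)
        assert g.degree("E1") == g.degree("B cells") == 1

    def test_common_exemplar_degree_ten(self):
        lmap = load_regulator_fixture()
        table = pd.DataFrame([
            {"exemplar": "E1", "genes": "A", "cell_types": ",".join(lmap.cell_types),
             "n_cell_types": 10, "specificity": "common"},
        ])
        g = build_cell_exemplar_bipartite(table)
        assert g.degree("E1") == 10

    def test_mixed_fixture_degrees_and_purity(self):
        table = pd.DataFrame([
            {"exemplar": "E1", "genes": "", "cell_types": "B cells",
             "n_cell_types": 1, "specificity": "lineage-specific"},
            {"exemplar": "E2", "genes": "", "cell_types": "B cells,abT cells",
             "n_cell_types": 2, "specificity": "shared"},
        ])
        g = build_cell_exemplar_bipartite(table)
        assert g.degree("B cells") == 2 and g.degree("abT cells") == 1
        assert g.degree("E1") == 1 and g.degree("E2") == 2
        for u, v in g.edges:
            assert g.nodes[u]["bipartite"] != g.nodes[v]["bipartite"]
        assert all("degree_class" in d for _, d in g.nodes(data=True))

    def test_multigraph_parallel_edges_per_exemplar(self, toy_lineage_map):
        # M1 holds genes from 2 exemplars, M2 from 1
        result = result_from_clusters({"G1": {"G1"}, "G2": {"G2"}, "G3": {"G3", "G4"}})
        g = build_regulator_module_multigraph(result, toy_lineage_map)
        assert g.number_of_edges("HLF", "M1") == 2
        first_m2_reg = sorted(
            r for (r, m) in toy_lineage_map.module_regulation if m == "M2"
        )[0]
        assert g.number_of_edges(first_m2_reg, "M2") == 1
        keys = {k for _, _, k in g.edges("HLF", keys=True)}
        assert keys == {"G1", "G2"}

    def test_regulator_driving_empty_module_is_isolated_from_exemplars(self):
        lmap = LineageMap(
            cell_types=["X"], regulators={"X": {"R1"}},
            module_assignment={}, module_regulation={("R1", "M1")},
        )
        g = build_regulator_module_multigraph(result_from_clusters({"G": {"G"}}), lmap)
        assert g.number_of_edges("R1", "M1") == 0
        assert "R1" in g.nodes


class TestModuleCoverage:
    def test_direct_ratio(self):
        net = ProteinNetwork.from_edges([("G1", "P"), ("G2", "P")])
        table = module_coverage({"G1": "M", "G2": "M", "G3": "M", "G4": "M"}, net)
        assert table.iloc[0]["coverage_pct"] == pytest.approx(50.0)

    def test_zero_interactor_module_flagged(self):
        net = ProteinNetwork.from_edges([("A", "B")])
        table = module_coverage({"G1": "M"}, net)
        assert bool(table.iloc[0]["zero_interactors"])

    def test_planted_coverage_recovered(self, standard_dataset):
        table = module_coverage(
            standard_dataset["lineage_map"].module_assignment,
            standard_dataset["network"],
        )
        planted = table[table["module_id"].str.startswith("M")]
        assert planted["coverage_pct"].mean() == pytest.approx(30.0, abs=5.0)
        decoys = table[table["module_id"].str.startswith("DECOY")]
        assert decoys["zero_interactors"].all() and len(decoys) == 2
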