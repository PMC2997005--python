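"""Report shapes: count tables, gene lookup, network edges, clustering."""

import numpy as np
import pandas as pd
import pytest

from pancmir import (
    build_count_table,
    cluster_heatmap_matrix,
    count_targets,
    gene_lookup,
    gene_lookup_table,
    network_edges,
)
from pancmir.datasets import (
    load_development_genes,
    load_published_gene_mirnas,
    load_published_groups,
    load_published_target_counts,
)
from pancmir.report import TOTAL_LABEL


class TestPublishedFixtures:
    def test_group_sizes(self):
        groups = load_published_groups()
        sizes = groups["group"].value_counts()
        assert len(groups) == 212
        assert sizes["I"] == 4 and sizes["II"] == 35 and sizes["III"] == 173

    def test_count_rows_respect_shared_bound(self):
        counts = load_published_target_counts()
        assert (
            counts["count_shared"]
            <= counts[["count_targetscan", "count_mirbase"]].min(axis=1)
        ).all()

    def test_count_mirnas_match_changing_groups(self):
        counts = load_published_target_counts()
        groups = load_published_groups()
        changing = set(groups.loc[groups["group"].isin(["I", "II"]), "mirna_id"])
        assert set(counts["mirna_id"]) == changing


class TestCountTable:
    def test_totals_rows_equal_column_sums(self):
        table = build_count_table(load_published_target_counts())
        for group in ("I", "II"):
            block = table[table["group"] == group]
            body = block[block["mirna_id"] != TOTAL_LABEL]
            total = block[block["mirna_id"] == TOTAL_LABEL].iloc[0]
            for col in ("count_targetscan", "count_mirbase", "count_shared"):
                assert total[col] == body[col].sum()

    def test_empty_records_give_all_zero_table(self):
        counts = count_targets({"TARGETSCAN": pd.DataFrame(columns=["mirna_id", "gene_id"])})
        assert len(counts) == 0

    def test_single_record_counts_by_scope_membership(self):
        rec = pd.DataFrame(
            [{"mirna_id": "miR-1", "gene_id": "G1", "group": "II"}]
        )
        empty = pd.DataFrame(columns=["mirna_id", "gene_id", "group"])
        counts = count_targets({"TARGETSCAN": rec, "MIRBASE": empty, "BOTH": empty})
        row = counts.set_index("mirna_id").loc["miR-1"]
        assert row["count_targetscan"] == 1
        assert row["count_mirbase"] == 0 and row["count_shared"] == 0

    def test_shared_bound_enforced_on_construction(self):
        rec_both = pd.DataFrame(
            [{"mirna_id": "miR-1", "gene_id": "G1", "group": "II"}]
        )
        empty = pd.DataFrame(columns=["mirna_id", "gene_id", "group"])
        with pytest.raises(ValueError, match="shared"):
            count_targets(
                {"TARGETSCAN": empty, "MIRBASE": empty, "BOTH": rec_both},
                on_shared_violation="raise",
            )


def _fixture_records():
    """Published gene-lookup fixture reshaped as screened records."""
    long = load_published_gene_mirnas()
    return long.rename(columns={"source": "sources"})[
        ["mirna_id", "gene_id", "group", "sources"]
    ]


class TestGeneLookup:
    def test_candidate_genes_with_hits(self):
        rows = gene_lookup(_fixture_records(), load_development_genes())
        with_hits = [r for r in rows if r.mirnas_by_source]
        assert len(rows) == 28
        assert len(with_hits) == 11

    def test_neurod1_has_five_targetscan_mirnas(self):
        rows = gene_lookup(_fixture_records(), ["NeuroD1"])
        hits = rows[0].mirnas_by_source["TARGETSCAN"]
        assert len(hits) == 5
        assert {m for m, _ in hits} == {
            "miR-17-5p",
            "miR-18a",
            "miR-92",
            "miR-103",
            "miR-494",
        }

    def test_distinct_group_two_mirnas(self):
        rows = gene_lookup(_fixture_records(), load_development_genes())
        group_two = {
            m
            for row in rows
            for hits in row.mirnas_by_source.values()
            for m, g in hits
            if g == "II"
        }
        assert len(group_two) == 19

    def test_gene_without_records_gets_zero_row(self):
        rows = gene_lookup(_fixture_records(), ["Pdx1"])
        assert rows[0].mirnas_by_source == {}
        table = gene_lookup_table(rows)
        assert table.iloc[0]["mirbase"] == "0"
        assert table.iloc[0]["targetscan"] == "0"

    def test_unknown_gene_reported_not_dropped(self):
        rows = gene_lookup(_fixture_records(), ["NOSUCHGENE"])
        assert rows[0].gene_id == "NOSUCHGENE"
        assert rows[0].mirnas_by_source == {}

    def test_empty_gene_list_gives_empty_output(self):
        assert gene_lookup(_fixture_records(), []) == []

    def test_lookup_is_complete_over_gene_list(self):
        records = _fixture_records()
        genes = load_development_genes()
        rows = gene_lookup(records, genes)
        nonempty = {r.gene_id.upper() for r in rows if r.mirnas_by_source}
        in_records = set(records["gene_id"].str.upper()) & {g.upper() for g in genes}
        assert nonempty == in_records


class TestNetworkEdges:
    def test_records_map_to_edges_one_to_one(self):
        records = pd.DataFrame(
            [
                {"mirna_id": "miR-1", "gene_id": "G1", "group": "II", "r": -0.99, "sources": "TARGETSCAN"},
                {"mirna_id": "miR-1", "gene_id": "G2", "group": "II", "r": -0.95, "sources": "TARGETSCAN"},
                {"mirna_id": "miR-2", "gene_id": "G1", "group": "I", "r": -0.92, "sources": "MIRBASE"},
            ]
        )
        edges = network_edges(records)
        assert len(edges) == 3
        assert edges["mirna_id"].nunique() == 2

    def test_duplicate_pair_across_scopes_merges_sources(self):
        scopes = {
            "TARGETSCAN": pd.DataFrame(
                [{"mirna_id": "miR-1", "gene_id": "G1", "group": "II", "r": -0.99, "sources": "TARGETSCAN"}]
            ),
            "MIRBASE": pd.DataFrame(
                [{"mirna_id": "miR-1", "gene_id": "G1", "group": "II", "r": -0.99, "sources": "MIRBASE"}]
            ),
        }
        edges = network_edges(scopes)
        assert len(edges) == 1
        assert edges.iloc[0]["sources"] == "MIRBASE+TARGETSCAN"

    def test_empty_records_give_empty_edge_list(self):
        assert len(network_edges(pd.DataFrame(columns=["mirna_id", "gene_id"]))) == 0

    def test_networkx_round_trip(self):
        records = pd.DataFrame(
            [{"mirna_id": "miR-1", "gene_id": "G1", "group": "II", "r": -0.9, "sources": "TARGETSCAN"}]
        )
        from pancmir.report import to_networkx

        graph = to_networkx(network_edges(records))
        assert graph.number_of_edges() == 1
        assert graph.nodes["miR-1"]["kind"] == "mirna"


class TestClusterHeatmap:
    def test_identical_rows_become_adjacent(self):
        matrix = pd.DataFrame(
            {
                "s1": [1.0, 9.0, 1.0],
                "s2": [2.0, 1.0, 2.0],
                "s3": [3.0, 5.0, 3.0],
            },
            index=["a", "b", "a2"],
        )
        ordered, order = cluster_heatmap_matrix(matrix)
        names = list(ordered.index)
        assert abs(names.index("a") - names.index("a2")) == 1

    def test_single_row_unchanged(self):
        matrix = pd.DataFrame({"s1": [1.0], "s2": [2.0]}, index=["a"])
        ordered, order = cluster_heatmap_matrix(matrix)
        pd.testing.assert_frame_equal(ordered, matrix)
        assert order == [0]

    def test_correlated_pair_merges_before_anticorrelated(self):
        # correlation distances by hand: d(x, 2x+1) = 0, d(x, -x) = 2,
        # so under average linkage x and 2x+1 join first and the leaf
        # order keeps them adjacent with -x outside the pair
        x = np.array([1.0, 2.0, 4.0])
        matrix = pd.DataFrame(
            [x, 2 * x + 1, -x], index=["x", "pos", "neg"], columns=["s1", "s2", "s3"]
        )
        _, order = cluster_heatmap_matrix(matrix)
        pos_idx = order.index(1)
        x_idx = order.index(0)
        neg_idx = order.index(2)
        assert abs(pos_idx - x_idx) == 1
        assert neg_idx in (0, 2)
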