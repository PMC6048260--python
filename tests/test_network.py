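import networkx as nx
import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

import halopond as hp
from halopond.network import (
    UNAFFILIATED,
    build_cooccurrence_graph,
    extract_subnetworks,
    prevalence_filter,
    subnetwork_abundance,
    subnetwork_taxa,
)

from conftest import make_table, make_taxonomy


class TestPrevalenceFilter:
    def test_eleven_reads_in_five_of_sixteen_retained(self):
        row = [11] * 5 + [0] * 11
        table = make_table({"keep": row, "pad": [1] * 16})
        out = prevalence_filter(table, min_reads=10, min_samples=5)
        assert "keep" in out.otu_ids

    def test_exactly_ten_reads_fails_strict_rule(self):
        table = make_table({"edge": [10] * 16, "pad": [11] * 16})
        out = prevalence_filter(table, min_reads=10, min_samples=5)
        assert out.otu_ids == ["pad"]

    def test_degenerate_thresholds_are_identity(self, toy_table):
        out = prevalence_filter(toy_table, min_reads=-1, min_samples=0)
        assert out.otu_ids == toy_table.otu_ids

    def test_min_samples_above_sample_count_rejected(self, toy_table):
        with pytest.raises(ValueError):
            prevalence_filter(toy_table, 10, 99)


def pairs_df(rows):
    return pd.DataFrame(rows, columns=["otu_a", "otu_b", "r", "p", "q"])


class TestEdgeRule:
    def test_r_exactly_at_threshold_is_no_edge(self):
        pairs = pairs_df([("a", "b", 0.98, 1e-6, 1e-5)])
        g = build_cooccurrence_graph(pairs, ["a", "b"])
        assert g.number_of_edges() == 0

    def test_above_both_thresholds_is_edge(self):
        pairs = pairs_df([("a", "b", 0.99, 1e-3, 0.04)])
        g = build_cooccurrence_graph(pairs, ["a", "b"])
        assert g.has_edge("a", "b")
        assert g["a"]["b"]["r"] == 0.99

    def test_q_max_zero_gives_empty_edge_set(self):
        pairs = pairs_df([("a", "b", 0.999, 0.0, 0.0)])
        g = build_cooccurrence_graph(pairs, ["a", "b"], q_max=0.0)
        assert g.number_of_edges() == 0

    def test_monotone_in_both_thresholds(self):
        rng = np.random.default_rng(5)
        ids = [f"o{i}" for i in range(30)]
        rows = []
        for i in range(30):
            for j in range(i + 1, 30):
                rows.append((ids[i], ids[j], rng.uniform(0.9, 1), 0.0, rng.uniform(0, 0.1)))
        pairs = pairs_df(rows)
        base = set(build_cooccurrence_graph(pairs, ids, r_min=0.98, q_max=0.05).edges)
        looser = set(build_cooccurrence_graph(pairs, ids, r_min=0.95, q_max=0.08).edges)
        assert base <= looser

    def test_edge_set_invariant_under_otu_reordering(self, planted_results):
        qc_table, _, res, _ = planted_results
        shuffled = qc_table.with_counts(qc_table.counts.iloc[::-1])
        res2 = hp.CooccurrenceModel(shuffled).fit()
        assert set(res.graph.edges) == set(res2.graph.edges)


class TestExtractSubnetworks:
    def _component_graph(self, sizes):
        g = nx.Graph()
        start = 0
        for s in sizes:
            nodes = [f"n{start + i:03d}" for i in range(s)]
            nx.add_path(g, nodes)
            start += s
        return g

    def test_eleven_node_component_is_major(self):
        assign = extract_subnetworks(self._component_graph([11]), 10)
        assert set(assign) == {"A"}

    def test_ten_node_component_is_unaffiliated(self):
        assign = extract_subnetworks(self._component_graph([10]), 10)
        assert set(assign) == {UNAFFILIATED}

    def test_edgeless_graph_all_unaffiliated(self):
        g = nx.Graph()
        g.add_nodes_from("abcdef")
        assert set(extract_subnetworks(g, 10)) == {UNAFFILIATED}

    def test_majors_ordered_by_descending_size(self):
        assign = extract_subnetworks(self._component_graph([12, 20, 15]), 10)
        sizes = assign.value_counts()
        assert sizes["A"] == 20 and sizes["B"] == 15 and sizes["C"] == 12

    def test_labels_partition_nodes(self, planted_results):
        _, _, res, _ = planted_results
        assert set(res.assignment.index) == set(res.graph.nodes)
        counts = res.node_counts()
        assert counts.sum() == res.graph.number_of_nodes()


class TestAttribution:
    def test_single_member_abundance_passthrough(self):
        assign = pd.Series({"a": "A"})
        fractions = pd.DataFrame({"S1": [0.10, 0.9]}, index=["a", "rest"])
        ab = subnetwork_abundance(assign, fractions)
        assert ab.loc["A", "S1"] == pytest.approx(0.10)
        assert ab.loc["filtered", "S1"] == pytest.approx(0.90)

    def test_full_assignment_conserves_mass(self):
        assign = pd.Series({"a": "A", "b": "A", "c": "B", "d": UNAFFILIATED})
        fractions = pd.DataFrame(
            {"S1": [0.4, 0.1, 0.3, 0.2], "S2": [0.25] * 4}, index=list("abcd")
        )
        ab = subnetwork_abundance(assign, fractions)
        assert np.allclose(ab.drop(index="filtered").sum(axis=0), 1.0, atol=1e-9)
        assert np.allclose(ab.loc["filtered"], 0.0, atol=1e-9)

    def test_missing_otu_in_fractions_errors(self):
        assign = pd.Series({"ghost": "A"})
        fractions = pd.DataFrame({"S1": [1.0]}, index=["real"])
        with pytest.raises(KeyError):
            subnetwork_abundance(assign, fractions)

    def test_planted_block_abundance_recovered(self, planted_results):
        qc_table, _, res, truth = planted_results
        ab = res.subnetwork_abundance()
        # per-sample totals conserve mass
        assert np.allclose(ab.sum(axis=0), 1.0, atol=1e-9)
        # the block dominating site 1 was planted at ~0.5 of that site's reads
        prof = truth.config.profiles()
        site0_samples = [s for s in qc_table.sample_ids if s.startswith("2CL")]
        # chloroplast removal renormalises the remaining read mass upward
        contam = truth.config.sites[0].contaminant_fraction
        planted_mass = prof[:, 0].sum() / (1 - contam)
        major_mass = ab.loc[res.major_labels, site0_samples].sum(axis=0)
        assert np.allclose(major_mass, planted_mass, atol=0.1)


class TestTaxa:
    def test_single_phylum_composition(self):
        assign = pd.Series({"a": "A", "b": "A"})
        tax = make_taxonomy(["a", "b"], phylum="Euryarchaeota")
        comp = subnetwork_taxa(assign, tax, "phylum")
        assert comp.loc[0, "fraction_by_count"] == 1.0

    def test_two_to_one_split(self):
        assign = pd.Series({"a": "A", "b": "A", "c": "A"})
        tax = make_taxonomy(
            ["a", "b", "c"],
            phylum={"a": "Proteobacteria", "b": "Proteobacteria", "c": "Euryarchaeota"},
        )
        comp = subnetwork_taxa(assign, tax, "phylum").set_index("phylum")
        assert comp.loc["Proteobacteria", "fraction_by_count"] == pytest.approx(2 / 3)
        assert comp.loc["Euryarchaeota", "fraction_by_count"] == pytest.approx(1 / 3)

    def test_unclassified_is_its_own_category(self):
        assign = pd.Series({"a": "A"})
        tax = make_taxonomy(["a"], phylum="unclassified")
        comp = subnetwork_taxa(assign, tax, "phylum")
        assert comp.loc[0, "phylum"] == "unclassified"

    def test_fractions_sum_to_one_per_label(self, planted_results):
        _, _, res, _ = planted_results
        comp = res.subnetwork_taxa("phylum")
        sums = comp.groupby("subnetwork")["fraction_by_count"].sum()
        assert np.allclose(sums, 1.0, atol=1e-9)


class TestModel:
    def test_planted_blocks_recovered(self, planted_results):
        _, _, res, truth = planted_results
        truth_labels = truth.block_labels.loc[res.assignment.index]
        assert adjusted_rand_score(truth_labels, res.assignment) >= 0.9

    def test_summary_mentions_parameters(self, planted_results):
        _, _, res, _ = planted_results
        text = res.summary()
        assert "r > 0.98" in text and "q < 0.05" in text

    def test_zero_variance_nodes_stay_unaffiliated(self):
        rows = {"flat": [20] * 16}
        rng = np.random.default_rng(0)
        for i in range(3):
            rows[f"o{i}"] = rng.integers(11, 300, 16).tolist()
        table = make_table(rows)
        res = hp.CooccurrenceModel(table, min_reads=10, min_samples=5).fit()
        assert res.assignment["flat"] == UNAFFILIATED

    def test_relabel_by_dominant_site_permutes_majors(self, planted_results):
        _, _, res, _ = planted_results
        relabeled = res.relabel_by_dominant_site()
        assert sorted(relabeled.major_labels) == sorted(res.major_labels)
        assert (relabeled.assignment == UNAFFILIATED).sum() == (
            res.assignment == UNAFFILIATED
        ).sum()

    def test_graphml_export_roundtrips(self, planted_results, tmp_path):
        _, _, res, _ = planted_results
        path = tmp_path / "net.graphml"
        res.to_graphml(path)
        g = nx.read_graphml(path)
        assert g.number_of_nodes() == res.graph.number_of_nodes()
        assert g.number_of_edges() == res.graph.number_of_edges()
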