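"""Relevance-network construction, merging and export."""

import numpy as np
import pandas as pd
import pytest

from metadigest import network as net
from metadigest import spls as mspls
from metadigest.io import AssignmentMap
from metadigest.simulate import SPLS_TRAITS, SyntheticConfig, generate_dataset


def sim_of(values, buckets, traits=("AMEn", "CDU_S")):
    df = pd.DataFrame(values, index=buckets, columns=list(traits))
    return mspls.SimilarityMatrix(df, (1,))


class TestBuildNetwork:
    def test_strict_cutoff(self):
        sim = sim_of([[0.6, -0.4], [0.2, 0.9]], ["b1", "b2"])
        g = net.build_network(sim, cutoff=0.5)
        assert g.n_edges == 2
        assert g.edge_scores()[("b1", "AMEn")] == 0.6
        assert g.edge_scores()[("b2", "CDU_S")] == 0.9

    def test_cutoff_zero_keeps_all_nonzero(self):
        sim = sim_of([[0.1, 0.0], [-0.2, 0.3]], ["b1", "b2"])
        assert net.build_network(sim, cutoff=0.0).n_edges == 3

    def test_exact_half_draws_no_edge(self):
        sim = sim_of([[0.5, -0.5]], ["b1"])
        g = net.build_network(sim, cutoff=0.5)
        assert g.n_edges == 0 and g.graph.number_of_nodes() == 0

    def test_no_isolated_nodes(self):
        sim = sim_of([[0.9, 0.1], [0.1, 0.2]], ["b1", "b2"])
        g = net.build_network(sim, cutoff=0.5)
        assert set(g.graph.nodes) == {"b1", "AMEn"}

    def test_edge_count_monotone_in_cutoff(self, rng):
        sim = sim_of(rng.uniform(-1, 1, (10, 2)),
                     [f"b{j}" for j in range(10)])
        counts = [net.build_network(sim, cutoff=c).n_edges
                  for c in (0.0, 0.3, 0.6, 0.9)]
        assert counts == sorted(counts, reverse=True)

    def test_invalid_cutoff(self):
        with pytest.raises(ValueError):
            net.build_network(sim_of([[0.9]], ["b1"]), cutoff=1.0)


def two_glucose_network():
    sim = sim_of([[0.8, 0.2], [0.6, 0.1], [0.7, 0.9]],
                 ["c1", "c2", "c3"])
    amap = AssignmentMap({"c1": ["Glucose"], "c2": ["Glucose"],
                          "c3": []})
    g = net.build_network(sim, cutoff=0.5, compartment="caecum",
                          assignment=amap)
    return g, amap


class TestMergeNetworks:
    def test_shared_metabolite_collapses_to_strongest_bucket(self):
        g, amap = two_glucose_network()
        merged = net.merge_networks([g], maps={"caecum": amap})
        # c3 is unassigned and dropped; c1/c2 collapse onto c1 (|0.8| > |0.6|)
        assert merged.bucket_nodes == ["Glucose (C)"]
        assert merged.graph.nodes["Glucose (C)"]["representative_bucket"] == "c1"
        assert merged.edge_scores()[("Glucose (C)", "AMEn")] == 0.8

    def test_fully_unassigned_network_vanishes(self):
        sim = sim_of([[0.9, 0.8]], ["u1"])
        g = net.build_network(sim, cutoff=0.5, compartment="ileum",
                              assignment=AssignmentMap({"u1": []}))
        g2, amap2 = two_glucose_network()
        merged = net.merge_networks([g, g2], maps={
            "ileum": AssignmentMap({"u1": []}), "caecum": amap2})
        assert all(n.endswith("(C)") for n in merged.bucket_nodes)

    def test_merge_idempotent(self):
        g, amap = two_glucose_network()
        once = net.merge_networks([g], maps={"caecum": amap})
        twice = net.merge_networks([once])
        assert set(once.graph.nodes) == set(twice.graph.nodes)
        assert once.edge_scores() == twice.edge_scores()
        for n in once.graph.nodes:
            assert once.graph.nodes[n] == twice.graph.nodes[n]

    def test_every_merged_score_exists_in_a_source(self, rng):
        ds = generate_dataset(SyntheticConfig(seed=3))
        nets, maps, sources = [], {}, set()
        for comp, table in ds.buckets.items():
            m = mspls.fit_spls_canonical(
                table.data, ds.traits.data[list(SPLS_TRAITS)],
                H=2, keep_x=mspls.keep_quarter(table.data.shape[1]))
            g = net.build_network(mspls.similarity_matrix(m), cutoff=0.5,
                                  compartment=comp,
                                  assignment=ds.assignments[comp])
            nets.append(g)
            maps[comp] = ds.assignments[comp]
            sources |= set(g.edge_scores().values())
        merged = net.merge_networks(nets, maps=maps)
        assert set(merged.edge_scores().values()) <= sources

    def test_node_count_matches_ground_truth_oracle(self):
        # disjoint per-compartment metabolite labels: merged node count =
        # sum of distinct assigned labels with edges + shared trait nodes
        for seed in range(3):
            ds = generate_dataset(SyntheticConfig(seed=seed))
            nets, maps = [], {}
            expected_labels = set()
            trait_nodes = set()
            for comp, table in ds.buckets.items():
                m = mspls.fit_spls_canonical(
                    table.data, ds.traits.data[list(SPLS_TRAITS)],
                    H=2, keep_x=mspls.keep_quarter(table.data.shape[1]))
                g = net.build_network(mspls.similarity_matrix(m), cutoff=0.5,
                                      compartment=comp,
                                      assignment=ds.assignments[comp])
                nets.append(g)
                maps[comp] = ds.assignments[comp]
                amap = ds.assignments[comp]
                for b in g.bucket_nodes:
                    label = amap.label_for(b)
                    if label is not None:
                        expected_labels.add((label, comp))
                trait_nodes |= set(g.trait_nodes)
            merged = net.merge_networks(nets, maps=maps)
            assert len(merged.bucket_nodes) == len(expected_labels)
            assert set(merged.trait_nodes) == trait_nodes


class TestExport:
    def test_sif_line_per_edge(self, tmp_path):
        g, _ = two_glucose_network()
        p = net.export_network(g, tmp_path / "n.sif", "sif")
        lines = p.read_text().strip().splitlines()
        assert len(lines) == g.n_edges
        assert all(len(l.split("\t")) == 3 and l.split("\t")[1] == "assoc"
                   for l in lines)

    def test_graphml_round_trip_exact(self, tmp_path):
        g, amap = two_glucose_network()
        merged = net.merge_networks([g], maps={"caecum": amap})
        for n in (g, merged):
            p = net.export_network(n, tmp_path / "n.graphml", "graphml")
            back = net.read_graphml(p)
            assert set(back.graph.nodes) == set(n.graph.nodes)
            assert back.edge_scores() == n.edge_scores()  # scores exact
            for node in n.graph.nodes:
                assert back.graph.nodes[node] == n.graph.nodes[node]

    def test_tsv_edge_list(self, tmp_path):
        g, _ = two_glucose_network()
        p = net.export_network(g, tmp_path / "n.tsv", "tsv")
        df = pd.read_csv(p, sep="\t")
        assert len(df) == g.n_edges
        assert set(df.columns) == {"source", "target", "score"}

    def test_unknown_format(self, tmp_path):
        g, _ = two_glucose_network()
        with pytest.raises(ValueError):
            net.export_network(g, tmp_path / "x", "dot")
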