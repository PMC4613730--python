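"""Network assembly, hub detection, common modules, stage comparison."""

import logging

import pytest

from conftest import make_catalog, random_catalog
from fflnet import (COMPOSITE, FFLInstance, GENE, MIRNA, MIRNA_FFL,
                    StageNetwork, TF, TF_FFL, build_network, common_modules,
                    compare_stages, enumerate_ffls, find_hub_pairs,
                    find_hub_regulators, network_summary, summarize_ffls)


def _ffl(tf, mirna, gene, t=TF_FFL):
    return FFLInstance(tf, mirna, gene, t)


class TestBuildNetwork:
    def test_single_tf_ffl_three_edges(self):
        net = build_network([_ffl("A", "m", "g")], "S")
        assert network_summary(net) == (3, 1, 1, 1)
        assert net.edges == {("A", "g", TF), ("m", "g", MIRNA),
                             ("A", "m", TF)}

    def test_composite_adds_reverse_edge(self):
        net = build_network([_ffl("A", "m", "g", COMPOSITE)], "S")
        assert net.n_edges == 4
        assert ("m", "A", MIRNA) in net.edges

    def test_shared_pair_union(self):
        net = build_network([_ffl("A", "m", "g1"), _ffl("A", "m", "g2")], "S")
        assert len(net.nodes) == 4
        assert net.n_edges == 5

    def test_empty(self):
        assert network_summary(build_network([], "S")) == (0, 0, 0, 0)

    def test_edge_count_bound(self, rng):
        for _ in range(20):
            cand, cat = random_catalog(rng, 5, 5, 8, density=0.3)
            ffls = enumerate_ffls(cand, cat)
            s = summarize_ffls(ffls, "S")
            net = build_network(ffls, "S")
            assert net.n_edges <= (3 * (s.n_tf_ffl + s.n_mirna_ffl)
                                   + 4 * s.n_composite)


class TestHubRegulators:
    def test_single_node_class_uses_fallback_and_logs(self, caplog):
        net = build_network([_ffl("A", "m", "g")], "S")
        with caplog.at_level(logging.WARNING, logger="fflnet.network"):
            hub_tfs, hub_mirnas = find_hub_regulators(net)
        assert hub_tfs == ["A"]
        assert hub_mirnas == ["m"]
        assert "falling back" in caplog.text

    def test_all_out_fractions_tied_fall_back_to_top_out_degree(self):
        # two TFs, out-degrees 5 and 1, every edge outgoing
        net = StageNetwork(stage="S")
        for i in range(5):
            net.add_edge("A", TF, f"g{i}", GENE)
        net.add_edge("B", TF, "g0", GENE)
        hub_tfs, _ = find_hub_regulators(net, max_hubs=1)
        assert hub_tfs == ["A"]

    def test_strict_mean_filter(self):
        # TF "A" purely outgoing; TF "B" mostly incoming -> only A exceeds mean
        net = StageNetwork(stage="S")
        net.add_edge("A", TF, "g1", GENE)
        net.add_edge("A", TF, "g2", GENE)
        net.add_edge("B", TF, "g1", GENE)
        net.add_edge("m", MIRNA, "B", TF)
        net.add_edge("m2", MIRNA, "B", TF)
        hub_tfs, _ = find_hub_regulators(net)
        assert hub_tfs == ["A"]

    def test_cap_and_determinism_under_input_order(self, rng):
        cand, cat = random_catalog(rng, 12, 12, 15, density=0.4)
        ffls = enumerate_ffls(cand, cat)
        net = build_network(ffls, "S")
        tfs1, mirnas1 = find_hub_regulators(net)
        shuffled = list(ffls)
        rng.shuffle(shuffled)
        net2 = build_network(shuffled, "S")
        tfs2, mirnas2 = find_hub_regulators(net2)
        assert tfs1 == tfs2 and mirnas1 == mirnas2
        assert len(tfs1) <= 5 and len(mirnas1) <= 5


class TestHubPairs:
    def test_counts_above_mean(self):
        ffls = ([_ffl("A", "m1", f"g{i}") for i in range(4)]
                + [_ffl("B", "m2", "g9"), _ffl("C", "m3", "g9")])
        pairs = find_hub_pairs(ffls)
        # counts {4, 1, 1}, mean 2 -> only (A, m1)
        assert pairs == [("A", "m1", 4, False)]

    def test_degenerate_mean_fallback(self, caplog):
        with caplog.at_level(logging.WARNING, logger="fflnet.network"):
            pairs = find_hub_pairs([_ffl("A", "m", "g")])
        assert pairs == [("A", "m", 1, False)]
        assert "falling back" in caplog.text

    def test_mutual_flag_from_composite_and_catalog(self):
        ffls = [_ffl("A", "m", "g", COMPOSITE), _ffl("B", "m2", "g2")]
        pairs = find_hub_pairs(ffls)
        assert ("A", "m", 1, True) in pairs
        cat = make_catalog(tf_mirna=[("A", "m"), ("B", "m2")],
                           mirna_tf=[("m", "A")])
        pairs_cat = find_hub_pairs(ffls, catalog=cat)
        assert set(pairs_cat) == set(pairs)

    def test_empty(self):
        assert find_hub_pairs([]) == []


class TestCommonModules:
    def test_disjoint_networks_empty(self):
        a = build_network([_ffl("A", "m", "g")], "B1")
        b = build_network([_ffl("B", "m2", "g2")], "B2")
        assert common_modules([a, b]) == []

    def test_identical_networks_single_full_module(self):
        ffls = [_ffl("A", "m", "g"), _ffl("B", "m", "g2", MIRNA_FFL)]
        nets = [build_network(ffls, s) for s in ("B1", "B2", "B3")]
        mods = common_modules(nets)
        assert len(mods) == 1
        assert mods[0].stages == frozenset({"B1", "B2", "B3"})
        assert mods[0].edges == nets[0].edges
        assert mods[0].nodes == nets[0].nodes

    def test_maximal_stage_sets_reported_once(self):
        shared_all = _ffl("A", "m", "g")
        shared_12 = _ffl("B", "m2", "g2")
        nets = [
            build_network([shared_all, shared_12], "S1"),
            build_network([shared_all, shared_12], "S2"),
            build_network([shared_all], "S3"),
        ]
        mods = common_modules(nets)
        by_stages = {mod.stages: mod for mod in mods}
        assert set(by_stages) == {frozenset({"S1", "S2", "S3"}),
                                  frozenset({"S1", "S2"})}
        all3 = by_stages[frozenset({"S1", "S2", "S3"})]
        assert all3.edges == build_network([shared_all], "x").edges

    def test_module_edges_subset_of_members(self, rng):
        nets = []
        for s in range(3):
            cand, cat = random_catalog(rng, 4, 4, 6, density=0.5)
            nets.append(build_network(enumerate_ffls(cand, cat), f"S{s}"))
        for mod in common_modules(nets):
            for stage in mod.stages:
                net = next(n for n in nets if n.stage == stage)
                assert mod.edges <= net.edges

    def test_requires_two_networks(self):
        with pytest.raises(ValueError):
            common_modules([StageNetwork(stage="A")])


class TestCompareStages:
    def test_identical_everything_shared(self):
        a = build_network([_ffl("A", "m", "g")], "B1")
        b = build_network([_ffl("A", "m", "g")], "T1")
        comp = compare_stages(a, b)
        assert comp.shared_regulators == {"A", "m"}
        assert not comp.specific_to_a and not comp.specific_to_b
        assert comp.shared_targets == {"g"}

    def test_hand_built_shared_tcf3_ccnd2(self):
        a = build_network([_ffl("TCF3", "mir-1", "CCND2"),
                           _ffl("PAX5", "mir-1", "X")], "B1")
        b = build_network([_ffl("TCF3", "mir-2", "CCND2"),
                           _ffl("SPI1", "mir-2", "Y")], "T1")
        comp = compare_stages(a, b)
        assert "TCF3" in comp.shared_regulators
        assert comp.shared_targets == {"CCND2"}
        assert "PAX5" in comp.specific_to_a
        assert "SPI1" in comp.specific_to_b

    def test_partition_invariant(self, rng):
        cand, cat = random_catalog(rng, 6, 6, 8, density=0.4)
        a = build_network(enumerate_ffls(cand, cat), "A")
        cand2, cat2 = random_catalog(rng, 6, 6, 8, density=0.4)
        b = build_network(enumerate_ffls(cand2, cat2), "B")
        comp = compare_stages(a, b)
        reg_a = a.nodes_of_class(TF) | a.nodes_of_class(MIRNA)
        assert comp.shared_regulators | comp.specific_to_a == reg_a
        assert not comp.shared_regulators & comp.specific_to_a
        assert not comp.specific_to_a & comp.specific_to_b
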