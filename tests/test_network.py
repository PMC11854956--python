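import itertools

import pandas as pd
import pytest

from saltnet.models import InputError
from saltnet.network import (
    annotate_hubs,
    build_network,
    export_network,
    read_graphml,
)


def de(ids_status):
    return pd.DataFrame(
        {"status": list(ids_status.values())},
        index=pd.Index(list(ids_status), name="feature_id"),
    )


def simple_inputs():
    de_by_class = {
        "miRNA": de({"miR1": "up", "miR2": "down", "miR3": "ns"}),
        "mRNA": de({"m1": "down", "m2": "up", "m3": "ns"}),
        "lncRNA": de({"l1": "up", "l2": "ns"}),
        "circRNA": de({"c1": "down"}),
    }
    targets = pd.DataFrame([
        dict(mirna_id="miR1", target_id="m1", allen_score=2.0, mfe_ratio=0.9),
        dict(mirna_id="miR1", target_id="m3", allen_score=1.0, mfe_ratio=0.9),  # m3 ns
        dict(mirna_id="miR3", target_id="m2", allen_score=1.0, mfe_ratio=0.9),  # miR3 ns
        dict(mirna_id="miR2", target_id="m2", allen_score=3.0, mfe_ratio=0.8),
    ])
    mimics = pd.DataFrame([
        dict(mirna_id="miR1", ncrna_id="l1", bulge_length=2, allen_score=4.0),
        dict(mirna_id="miR1", ncrna_id="l2", bulge_length=2, allen_score=4.0),  # l2 ns
        dict(mirna_id="miR2", ncrna_id="c1", bulge_length=3, allen_score=5.0),
    ])
    return de_by_class, targets, mimics


class TestBuild:
    def test_edges_require_both_ends_differential(self):
        de_by_class, targets, mimics = simple_inputs()
        net = build_network(de_by_class, targets, mimics)
        assert net.edges == {
            ("m1", "miR1"), ("m2", "miR2"), ("l1", "miR1"), ("c1", "miR2")
        }
        assert set(net.nodes) == {"miR1", "miR2", "m1", "m2", "l1", "c1"}

    def test_triples_share_the_mirna(self):
        de_by_class, targets, mimics = simple_inputs()
        net = build_network(de_by_class, targets, mimics)
        assert net.triples == [("miR1", "m1", "l1"), ("miR2", "m2", "c1")]

    def test_multiple_sites_collapse_to_best_evidence(self):
        de_by_class, targets, mimics = simple_inputs()
        extra = pd.concat([
            targets,
            pd.DataFrame([dict(mirna_id="miR1", target_id="m1",
                               allen_score=0.5, mfe_ratio=1.0)]),
        ], ignore_index=True)
        net = build_network(de_by_class, extra, mimics)
        assert net.graph.edges["miR1", "m1"]["allen_score"] == 0.5

    def test_node_attributes(self):
        de_by_class, targets, mimics = simple_inputs()
        net = build_network(de_by_class, targets, mimics)
        assert net.graph.nodes["miR1"]["rna_class"] == "miRNA"
        assert net.graph.nodes["miR1"]["de_status"] == "up"
        assert net.graph.nodes["c1"]["rna_class"] == "circRNA"
        assert net.graph.edges["miR1", "l1"]["edge_kind"] == "mimic"

    def test_include_isolated_nodes(self):
        de_by_class, targets, mimics = simple_inputs()
        de_by_class["lncRNA"] = de({"l1": "up", "l2": "ns", "l3": "up"})
        net = build_network(de_by_class, targets, mimics, include_isolated=True)
        assert "m3" not in net.graph  # not differential
        assert "l2" not in net.graph  # not differential
        assert "l3" in net.graph      # differential but edgeless

    def test_duplicate_feature_id_across_classes_rejected(self):
        de_by_class, targets, mimics = simple_inputs()
        de_by_class["mRNA"] = de({"miR1": "up"})
        with pytest.raises(InputError):
            build_network(de_by_class, targets, mimics)

    def test_empty_inputs_give_empty_network(self):
        de_by_class, _, _ = simple_inputs()
        net = build_network(de_by_class, pd.DataFrame(), pd.DataFrame())
        assert net.nodes == [] and net.triples == []


class TestHubsAndSponges:
    def _star(self, n_targets, n_mimic_ncrnas=0):
        mirna = {"miR1": "up"}
        mrnas = {f"m{i}": "up" for i in range(n_targets)}
        lncs = {f"l{i}": "up" for i in range(n_mimic_ncrnas)}
        de_by_class = {
            "miRNA": de(mirna), "mRNA": de(mrnas), "lncRNA": de(lncs),
            "circRNA": de({}),
        }
        targets = pd.DataFrame([
            dict(mirna_id="miR1", target_id=t, allen_score=1.0, mfe_ratio=0.9)
            for t in mrnas
        ])
        mimics = pd.DataFrame([
            dict(mirna_id="miR1", ncrna_id=l, bulge_length=1, allen_score=2.0)
            for l in lncs
        ])
        return build_network(de_by_class, targets, mimics)

    def test_hub_is_strictly_greater_than_six(self):
        net6 = annotate_hubs(self._star(6))
        assert net6.graph.nodes["miR1"]["hub"] is False
        net7 = annotate_hubs(self._star(7))
        assert net7.graph.nodes["miR1"]["hub"] is True

    def test_sponge_needs_two_mirnas(self):
        de_by_class = {
            "miRNA": de({"miR1": "up", "miR2": "down"}),
            "mRNA": de({}), "circRNA": de({}),
            "lncRNA": de({"l1": "up", "l2": "up"}),
        }
        mimics = pd.DataFrame([
            dict(mirna_id="miR1", ncrna_id="l1", bulge_length=1, allen_score=1.0),
            dict(mirna_id="miR2", ncrna_id="l1", bulge_length=1, allen_score=1.0),
            dict(mirna_id="miR1", ncrna_id="l2", bulge_length=1, allen_score=1.0),
        ])
        net = annotate_hubs(build_network(de_by_class, pd.DataFrame(), mimics))
        assert net.graph.nodes["l1"]["sponge"] is True
        assert net.graph.nodes["l2"]["sponge"] is False


class TestExport:
    def test_sif_lines(self, tmp_path):
        de_by_class, targets, mimics = simple_inputs()
        net = annotate_hubs(build_network(de_by_class, targets, mimics))
        (path,) = export_network(net, str(tmp_path / "net"), "SIF")
        lines = {tuple(l.split("\t")) for l in open(path).read().splitlines()}
        assert lines == {
            ("miR1", "targets", "m1"),
            ("miR2", "targets", "m2"),
            ("miR1", "sponged_by", "l1"),
            ("miR2", "sponged_by", "c1"),
        }

    def test_graphml_roundtrip_lossless(self, tmp_path):
        de_by_class, targets, mimics = simple_inputs()
        net = annotate_hubs(build_network(de_by_class, targets, mimics))
        (path,) = export_network(net, str(tmp_path / "net"), "GraphML")
        back = read_graphml(path)
        assert set(back.graph.nodes) == set(net.graph.nodes)
        assert back.edges == net.edges
        assert back.triples == net.triples
        for n, d in net.graph.nodes(data=True):
            assert back.graph.nodes[n]["rna_class"] == d["rna_class"]
            assert back.graph.nodes[n]["de_status"] == d["de_status"]
        for u, v, d in net.graph.edges(data=True):
            assert back.graph.edges[u, v]["edge_kind"] == d["edge_kind"]
            assert back.graph.edges[u, v]["allen_score"] == d["allen_score"]

    def test_tsv_export(self, tmp_path):
        de_by_class, targets, mimics = simple_inputs()
        net = annotate_hubs(build_network(de_by_class, targets, mimics))
        npath, epath = export_network(net, str(tmp_path / "net"), "TSV")
        nodes = pd.read_csv(npath, sep="\t")
        edges = pd.read_csv(epath, sep="\t")
        assert len(nodes) == net.graph.number_of_nodes()
        assert len(edges) == net.graph.number_of_edges()
        assert set(edges.mirna_id) <= {"miR1", "miR2"}

    def test_unknown_format_rejected(self, tmp_path):
        de_by_class, targets, mimics = simple_inputs()
        net = build_network(de_by_class, targets, mimics)
        with pytest.raises(InputError):
            export_network(net, str(tmp_path / "net"), "XGMML")

    def test_summary_counts(self):
        de_by_class, targets, mimics = simple_inputs()
        net = annotate_hubs(build_network(de_by_class, targets, mimics))
        s = net.summary()
        assert s["n_nodes"] == 6 and s["n_edges"] == 4 and s["n_triples"] == 2
        assert s["nodes_by_class"] == {
            "miRNA": 2, "mRNA": 2, "lncRNA": 1, "circRNA": 1
        }
        assert s["edges_by_kind"] == {"target": 2, "mimic": 2}
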