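"""Regulatory-graph assembly, FBL/FFL enumeration, hubs and exports."""

from collections import Counter

import numpy as np
import pandas as pd
import pytest

from mircoreg.motifs import (
    MotifInstance,
    RegGraph,
    assemble_graph,
    common_regulators,
    core_members,
    degree_report,
    enumerate_ffl,
    export_network,
    find_fbl,
    motif_subgraph,
    motif_summary,
    read_graphml,
)
from mircoreg.targets import PairSet

from conftest import make_graph


def _brute_force(g: RegGraph):
    """Exhaustive pair/triple scan, written against the definitions only."""
    fbls, ffls = [], []
    tfs = g.nodes_with_role("TF")
    mirnas = g.nodes_with_role("miRNA")
    nodes = list(g.g.nodes)
    for t in tfs:
        for m in mirnas:
            if t == m:
                continue
            t2m, m2t = g.has_edge(t, m), g.has_edge(m, t)
            if t2m and m2t:
                fbls.append(MotifInstance("FBL", tf=t, mirna=m))
            for x in nodes:
                if x in (t, m) or g.roles(x) == {"miRNA"}:
                    continue
                if not (g.has_edge(t, x) and g.has_edge(m, x)):
                    continue
                if t2m and m2t:
                    ffls.append(MotifInstance("composite-FFL", tf=t, mirna=m, gene=x))
                elif t2m:
                    ffls.append(MotifInstance("TF-FFL", tf=t, mirna=m, gene=x))
                elif m2t:
                    ffls.append(MotifInstance("miRNA-FFL", tf=t, mirna=m, gene=x))
    return sorted(fbls, key=lambda i: (i.tf, i.mirna)), sorted(
        ffls, key=lambda i: (i.kind, i.tf, i.mirna, i.gene)
    )


def test_fbl_requires_reciprocity():
    g = make_graph(tm=[("t", "m")])
    assert find_fbl(g) == []
    g = make_graph(tm=[("t", "m")], mt=[("m", "t")])
    assert find_fbl(g) == [MotifInstance("FBL", tf="t", mirna="m")]


def test_ffl_definitions_and_composite_precedence():
    tf_ffl = make_graph(tm=[("t", "m")], tg=[("t", "x")], mg=[("m", "x")])
    assert enumerate_ffl(tf_ffl) == [MotifInstance("TF-FFL", "t", "m", "x")]
    mir_ffl = make_graph(mt=[("m", "t")], tg=[("t", "x")], mg=[("m", "x")])
    assert enumerate_ffl(mir_ffl) == [MotifInstance("miRNA-FFL", "t", "m", "x")]
    comp = make_graph(
        tm=[("t", "m")], mt=[("m", "t")], tg=[("t", "x")], mg=[("m", "x")]
    )
    # the composite triple is not double-counted as TF-/miRNA-FFL
    assert enumerate_ffl(comp) == [MotifInstance("composite-FFL", "t", "m", "x")]
    assert find_fbl(comp) == [MotifInstance("FBL", tf="t", mirna="m")]


def test_no_motif_without_joint_target():
    g = make_graph(tm=[("t", "m")], tg=[("t", "x")])
    assert enumerate_ffl(g) == []


def test_dual_role_target_slot():
    """A TF that is also regulated can fill the gene slot of an FFL."""
    g = RegGraph()
    for name, role in [("t", "TF"), ("m", "miRNA"), ("t2", "TF")]:
        g.add_node(name, role)
    g.add_node("t2", "gene")  # regulated TF: dual role
    g.add_edge("t", "m")
    g.add_edge("t", "t2")
    g.add_edge("m", "t2")
    assert enumerate_ffl(g) == [MotifInstance("TF-FFL", "t", "m", "t2")]


def test_enumeration_matches_brute_force_on_random_graphs(rng):
    for _ in range(25):
        tfs = [f"T{i}" for i in range(6)]
        mirnas = [f"miR-{i}" for i in range(5)]
        genes = [f"G{i}" for i in range(8)]
        g = RegGraph()
        for t in tfs:
            g.add_node(t, "TF")
        for m in mirnas:
            g.add_node(m, "miRNA")
        for x in genes:
            g.add_node(x, "gene")
        for t in tfs:
            for m in mirnas:
                if rng.random() < 0.25:
                    g.add_edge(t, m)
                if rng.random() < 0.25:
                    g.add_edge(m, t)
            for x in genes:
                if rng.random() < 0.25:
                    g.add_edge(t, x)
        for m in mirnas:
            for x in genes:
                if rng.random() < 0.25:
                    g.add_edge(m, x)
        fbls, ffls = _brute_force(g)
        assert find_fbl(g) == fbls
        assert enumerate_ffl(g) == ffls
        # partition property: every triple has exactly one kind
        assert len(set((i.tf, i.mirna, i.gene) for i in ffls)) == len(ffls)
        # composite => FBL
        fbl_pairs = {(i.tf, i.mirna) for i in fbls}
        for inst in ffls:
            if inst.kind == "composite-FFL":
                assert (inst.tf, inst.mirna) in fbl_pairs


def test_motif_summary_partition_totals():
    motifs = []
    for i in range(21):
        motifs.append(MotifInstance("miRNA-FFL", f"t{i}", "miR-a", f"g{i}"))
    for i in range(152):
        motifs.append(MotifInstance("TF-FFL", f"t{i}", "miR-b", f"h{i}"))
    for i in range(25):
        motifs.append(MotifInstance("composite-FFL", f"t{i}", "miR-c", f"k{i}"))
    table = motif_summary(motifs, de_mirnas=["miR-a", "miR-b", "miR-c", "miR-d"])
    assert table.loc["total", "total_ffl"] == 198
    assert table.loc["total", ["miRNA-FFL", "TF-FFL", "composite-FFL"]].tolist() == [
        21, 152, 25,
    ]
    # a miRNA in no motif gets an explicit all-zero row
    assert table.loc["miR-d"].sum() == 0


def test_degree_report_and_conservation(rng):
    g = make_graph(tg=[("t", f"x{i}") for i in range(5)])
    rep = degree_report(g, top_k=1)
    assert rep.iloc[0]["node"] == "t" and rep.iloc[0]["degree"] == 5
    assert rep.iloc[0]["rank"] == 1 and rep.iloc[0]["hub"]
    assert rep["degree"].sum() == 2 * g.n_edges
    # single edge: both endpoints degree 1; ties broken lexicographically
    g2 = make_graph(tg=[("a", "b")])
    rep2 = degree_report(g2)
    assert rep2["degree"].tolist() == [1, 1]
    assert rep2["node"].tolist() == ["a", "b"]


def test_common_regulators():
    tm = pd.DataFrame(
        {
            "tf": ["T1", "T1", "T2", "T3", "T3"],
            "mirna": ["miR-1", "miR-2", "miR-1", "miR-1", "miR-2"],
        }
    )
    assert common_regulators(tm, ["miR-1"]) == ["T1", "T2", "T3"]
    assert common_regulators(tm, ["miR-1", "miR-2"]) == ["T1", "T3"]
    assert common_regulators(tm, ["miR-1", "miR-3"]) == []
    with pytest.raises(ValueError):
        common_regulators(tm, [])


def test_core_members_requires_all_three_subnetworks():
    motifs = [
        MotifInstance("miRNA-FFL", "T1", "miR-1", "G1"),
        MotifInstance("TF-FFL", "T1", "miR-1", "G1"),
        MotifInstance("composite-FFL", "T1", "miR-1", "G1"),
        MotifInstance("TF-FFL", "T2", "miR-2", "G2"),  # one subnetwork only
    ]
    genes, mirnas, tfs = core_members(motifs)
    assert genes == ["G1"] and mirnas == ["miR-1"] and tfs == ["T1"]
    assert core_members([]) == ([], [], [])


def test_assemble_graph_restriction_and_roles():
    tm = pd.DataFrame(
        {"tf": ["T1", "T2"], "mirna": ["miR-1", "miR-9"], "source": ["CHEA", "CHEA"]}
    )
    tg = pd.DataFrame(
        {
            "tf": ["T1", "T1", "T3"],
            "gene": ["G1", "G9", "G1"],
            "sign": ["Activation", "Repression", "Activation"],
            "source": ["TRRUST"] * 3,
        }
    )
    pairs = PairSet()
    pairs.add("miR-1", "G1", predictor="x")
    pairs.add("miR-9", "G9", predictor="x")  # miR-9 not a DE miRNA
    g = assemble_graph(tm, tg, pairs, de_mirnas=["miR-1"])
    assert set(g.g.nodes) == {"miR-1", "T1", "G1"}
    assert g.roles("miR-1") == {"miRNA"}
    # miRNA edges are repression by construction
    assert g.g.edges["miR-1", "G1"]["sign"] == "repression"
    assert enumerate_ffl(g) == [MotifInstance("TF-FFL", "T1", "miR-1", "G1")]
    # empty miRNA list -> empty graph
    assert assemble_graph(tm, tg, pairs, de_mirnas=[]).n_nodes == 0


def test_assemble_graph_merges_duplicate_edges_with_provenance():
    tm = pd.DataFrame(
        {
            "tf": ["T1", "T1"],
            "mirna": ["miR-1", "miR-1"],
            "source": ["CHEA", "TransmiR"],
        }
    )
    tg = pd.DataFrame(columns=["tf", "gene", "sign", "source"])
    g = assemble_graph(tm, tg, PairSet(), de_mirnas=["miR-1"])
    assert g.n_edges == 1
    assert g.g.edges["T1", "miR-1"]["provenance"] == {"CHEA", "TransmiR"}


def test_sign_conflict_collapses_to_unknown():
    g = RegGraph()
    g.add_node("T1", "TF")
    g.add_node("G1", "gene")
    g.add_edge("T1", "G1", sign="activation")
    with pytest.warns(UserWarning, match="Conflicting"):
        g.add_edge("T1", "G1", sign="repression")
    assert g.g.edges["T1", "G1"]["sign"] == "unknown"


def test_untyped_node_rejected():
    g = RegGraph()
    g.add_node("T1", "TF")
    with pytest.raises(KeyError, match="G1"):
        g.add_edge("T1", "G1")


def test_export_sif_tokens(tmp_path):
    g = make_graph(tm=[("t", "m")], tg=[("t", "x")], mg=[("m", "x")])
    g.g.edges["t", "x"]["sign"] = "activation"
    path = tmp_path / "net.sif"
    export_network(g, path, fmt="sif")
    lines = sorted(path.read_text().strip().split("\n"))
    assert lines == ["m\trepresses\tx", "t\tactivates\tx", "t\tregulates\tm"]


def test_graphml_roundtrip(tmp_path):
    g = make_graph(
        tm=[("t", "m")], mt=[("m", "t")], tg=[("t", "x")], mg=[("m", "x")]
    )
    g.g.edges["t", "x"]["provenance"] = {"TRRUST"}
    path = tmp_path / "net.graphml"
    export_network(g, path, fmt="graphml")
    back = read_graphml(path)
    assert back == g


def test_graphml_roundtrip_at_coregulatory_scale(rng, tmp_path):
    """A ~93-node motif-scale graph survives export -> import losslessly."""
    g = RegGraph()
    tfs = [f"T{i}" for i in range(20)]
    mirnas = [f"miR-{i}" for i in range(6)]
    genes = [f"G{i}" for i in range(67)]
    for t in tfs:
        g.add_node(t, "TF")
    for m in mirnas:
        g.add_node(m, "miRNA")
    for x in genes:
        g.add_node(x, "gene")
    for t in tfs:
        for m in mirnas:
            if rng.random() < 0.3:
                g.add_edge(t, m)
        for x in genes:
            if rng.random() < 0.08:
                g.add_edge(t, x, sign="activation", provenance="TRRUST")
    for m in mirnas:
        for x in genes:
            if rng.random() < 0.15:
                g.add_edge(m, x, provenance="consensus")
    assert g.n_nodes == 93
    path = tmp_path / "big.graphml"
    export_network(g, path, fmt="graphml")
    assert read_graphml(path) == g


def test_export_errors(tmp_path):
    g = make_graph(tm=[("t", "m")])
    with pytest.raises(ValueError, match="format"):
        export_network(g, tmp_path / "x", fmt="gexf")
    with pytest.raises(ValueError, match="empty"):
        export_network(RegGraph(), tmp_path / "y", fmt="sif")


def test_motif_subgraph_scope():
    motifs = [
        MotifInstance("TF-FFL", "t", "m", "x"),
        MotifInstance("FBL", "t2", "m2"),
    ]
    sub = motif_subgraph(motifs)
    assert set(sub.g.nodes) == {"t", "m", "x", "t2", "m2"}
    assert sub.n_edges == 5
    rep = degree_report(sub, top_k=5)
    assert rep["degree"].sum() == 2 * sub.n_edges
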