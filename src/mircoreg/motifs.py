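"""miRNA-TF co-regulatory graph assembly and network-motif enumeration.

The regulatory graph is a typed, signed, directed graph over miRNA, TF and
gene nodes (an entity may carry both TF and gene roles). Two motif families
are enumerated:

* FBL (feedback loop): a reciprocal TF -> miRNA, miRNA -> TF pair.
* FFL (feed-forward loop): a TF t, miRNA m and joint target x (x not in
  {t, m}) with t and m both regulating x, classified by the master
  regulator — composite-FFL when t -> m and m -> t (mutual regulation),
  otherwise TF-FFL when t -> m, otherwise miRNA-FFL when m -> t. The
  classification is a partition: a triple has exactly one kind, with
  composite taking precedence, so per-kind counts sum to the FFL total.

miRNA edges are post-transcriptional repression by definition; TF -> target
edges carry activation/repression/unknown signs. Motif detection uses edge
presence and direction only, not sign.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable

import networkx as nx
import pandas as pd

from .targets import PairSet, normalize_gene, normalize_mirna

__all__ = [
    "RegGraph",
    "MotifInstance",
    "assemble_graph",
    "find_fbl",
    "enumerate_ffl",
    "motif_summary",
    "motif_subgraph",
    "degree_report",
    "common_regulators",
    "core_members",
    "export_network",
    "read_graphml",
    "MOTIF_KINDS",
]

MOTIF_KINDS = ("FBL", "miRNA-FFL", "TF-FFL", "composite-FFL")

ACTIVATION, REPRESSION, UNKNOWN = "activation", "repression", "unknown"
_SIGNS = {ACTIVATION, REPRESSION, UNKNOWN}


class RegGraph:
    """Typed, signed, directed regulatory graph backed by a networkx DiGraph.

    Node roles are stored as a set in the ``roles`` attribute ({"miRNA"},
    {"TF"}, {"gene"} or {"TF", "gene"} for dual-role entities). Duplicate
    (source, target) edges merge their provenance; conflicting signs collapse
    to ``unknown`` with a warning. miRNA-outgoing edges are always repression.
    """

    def __init__(self):
        self.g = nx.DiGraph()

    # -- construction -------------------------------------------------
    def add_node(self, name: str, role: str) -> None:
        if name in self.g:
            self.g.nodes[name]["roles"].add(role)
        else:
            self.g.add_node(name, roles={role})

    def add_edge(
        self,
        source: str,
        target: str,
        sign: str = UNKNOWN,
        provenance: str | None = None,
    ) -> None:
        if sign not in _SIGNS:
            raise ValueError(f"Unknown edge sign {sign!r}")
        for node in (source, target):
            if node not in self.g:
                raise KeyError(
                    f"Edge ({source!r} -> {target!r}) references untyped node {node!r};"
                    " add it with a role first"
                )
        if "miRNA" in self.g.nodes[source]["roles"]:
            sign = REPRESSION
        prov = {provenance} if provenance else set()
        if self.g.has_edge(source, target):
            data = self.g.edges[source, target]
            if data["sign"] != sign:
                warnings.warn(
                    f"Conflicting signs for edge {source} -> {target}; recording unknown",
                    stacklevel=2,
                )
                data["sign"] = UNKNOWN
            data["provenance"] |= prov
        else:
            self.g.add_edge(source, target, sign=sign, provenance=prov)

    # -- queries ------------------------------------------------------
    def nodes_with_role(self, role: str) -> list[str]:
        return sorted(n for n, d in self.g.nodes(data=True) if role in d["roles"])

    def roles(self, node: str) -> set[str]:
        return self.g.nodes[node]["roles"]

    def has_edge(self, u: str, v: str) -> bool:
        return self.g.has_edge(u, v)

    def successors(self, node: str) -> set[str]:
        return set(self.g.successors(node))

    def predecessors(self, node: str) -> set[str]:
        return set(self.g.predecessors(node))

    @property
    def n_nodes(self) -> int:
        return self.g.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.g.number_of_edges()

    def __eq__(self, other) -> bool:
        if not isinstance(other, RegGraph):
            return NotImplemented
        if set(self.g.nodes) != set(other.g.nodes):
            return False
        if any(self.roles(n) != other.roles(n) for n in self.g.nodes):
            return False
        if set(self.g.edges) != set(other.g.edges):
            return False
        return all(
            self.g.edges[e]["sign"] == other.g.edges[e]["sign"]
            and self.g.edges[e]["provenance"] == other.g.edges[e]["provenance"]
            for e in self.g.edges
        )


@dataclass(frozen=True)
class MotifInstance:
    """One FBL pair or FFL triple with its classified kind.

    ``gene`` is None for FBLs. ``edges`` lists the constituent directed edges.
    """

    kind: str
    tf: str
    mirna: str
    gene: str | None = None

    @property
    def members(self) -> tuple[str, ...]:
        return (self.tf, self.mirna) if self.gene is None else (
            self.tf, self.mirna, self.gene
        )

    @property
    def edges(self) -> tuple[tuple[str, str], ...]:
        t, m, x = self.tf, self.mirna, self.gene
        if self.kind == "FBL":
            return ((t, m), (m, t))
        if self.kind == "composite-FFL":
            return ((t, m), (m, t), (t, x), (m, x))
        if self.kind == "TF-FFL":
            return ((t, m), (t, x), (m, x))
        if self.kind == "miRNA-FFL":
            return ((m, t), (t, x), (m, x))
        raise ValueError(f"Unknown motif kind {self.kind!r}")


def assemble_graph(
    tf_mirna: pd.DataFrame,
    tf_gene: pd.DataFrame,
    mirna_targets: PairSet,
    de_mirnas: Iterable[str],
) -> RegGraph:
    """Build the co-regulatory graph around a set of differentially expressed miRNAs.

    ``tf_mirna`` needs columns (tf, mirna[, source]); ``tf_gene`` needs
    (tf, gene[, sign, source]) with TRRUST-style signs Activation / Repression /
    Unknown; ``mirna_targets`` is the consensus/validated miRNA-target set.
    The graph is restricted to the DE miRNAs, the TFs linked to them (in
    either direction) and their targets: TF -> gene edges are kept only when
    the gene is itself a retained miRNA target or TF.
    """
    de = {normalize_mirna(m) for m in de_mirnas}
    if not de:
        g = RegGraph()
        return g

    g = RegGraph()
    for m in sorted(de):
        g.add_node(m, "miRNA")

    # miRNA -> target edges (targets may be TFs, handled as dual-role below)
    mt_edges = [
        (m, t, prov) for (m, t), prov in sorted(mirna_targets.items()) if m in de
    ]
    tm_rows = [
        (str(r["tf"]), normalize_mirna(str(r["mirna"])), str(r.get("source", "")))
        for _, r in tf_mirna.iterrows()
    ]
    tm_rows = [(t, m, s) for (t, m, s) in tm_rows if m in de]

    tf_universe = {t for (t, _, _) in tm_rows}
    target_universe = {t for (_, t, _) in mt_edges}
    # TFs repressed by a DE miRNA join the TF universe when they also regulate
    tf_universe |= {x for x in target_universe if x in set(tf_gene["tf"].astype(str))}

    for t in sorted(tf_universe):
        g.add_node(t, "TF")
    for x in sorted(target_universe):
        g.add_node(x, "gene")  # dual role when x is also a TF

    for t, m, s in tm_rows:
        g.add_edge(t, m, sign=UNKNOWN, provenance=s or None)
    for m, x, prov in mt_edges:
        label = "validated" if prov.validated else "|".join(sorted(prov.predictors))
        g.add_edge(m, x, sign=REPRESSION, provenance=label or None)

    node_set = set(g.g.nodes)
    for _, r in tf_gene.iterrows():
        t = str(r["tf"])
        x = normalize_gene(str(r["gene"]))
        if t not in tf_universe or x not in node_set or x == t:
            continue
        sign = str(r.get("sign", "Unknown")).strip().lower()
        if sign not in _SIGNS:
            sign = UNKNOWN
        if x in g.g.nodes and "TF" in g.roles(x):
            g.add_node(x, "gene")  # regulated TF gains the gene role
        g.add_edge(t, x, sign=sign, provenance=str(r.get("source", "")) or None)
    return g


def find_fbl(g: RegGraph) -> list[MotifInstance]:
    """All reciprocal TF <-> miRNA pairs, deduplicated and sorted."""
    out = []
    for m in g.nodes_with_role("miRNA"):
        for t in g.successors(m):
            if "TF" in g.roles(t) and g.has_edge(t, m):
                out.append(MotifInstance("FBL", tf=t, mirna=m))
    return sorted(out, key=lambda i: (i.tf, i.mirna))


def enumerate_ffl(g: RegGraph) -> list[MotifInstance]:
    """Enumerate and classify every feed-forward loop in the graph.

    For each (TF t, miRNA m) with at least one regulatory edge between them,
    every joint target x (successor of both, x not in {t, m}, x not a pure
    miRNA) yields one motif: composite-FFL when the t/m edge is reciprocal,
    TF-FFL when only t -> m, miRNA-FFL when only m -> t.
    """
    out = []
    mirnas = g.nodes_with_role("miRNA")
    tfs = g.nodes_with_role("TF")
    for t in tfs:
        succ_t = g.successors(t)
        for m in mirnas:
            if m == t:
                continue
            t2m = g.has_edge(t, m)
            m2t = g.has_edge(m, t)
            if not (t2m or m2t):
                continue
            common = (succ_t & g.successors(m)) - {t, m}
            if not common:
                continue
            if t2m and m2t:
                kind = "composite-FFL"
            elif t2m:
                kind = "TF-FFL"
            else:
                kind = "miRNA-FFL"
            for x in sorted(common):
                if g.roles(x) == {"miRNA"}:
                    continue  # target slot is a gene (possibly a dual-role TF)
                out.append(MotifInstance(kind, tf=t, mirna=m, gene=x))
    return sorted(out, key=lambda i: (i.kind, i.tf, i.mirna, i.gene))


def motif_summary(
    motifs: Iterable[MotifInstance], de_mirnas: Iterable[str] | None = None
) -> pd.DataFrame:
    """Per-miRNA motif participation counts with a grand-total row.

    One row per miRNA with columns FBL, miRNA-FFL, TF-FFL, composite-FFL and
    total_ffl; miRNAs in no motif get explicit zero rows. The final ``total``
    row sums each column, so total FFLs equal the per-kind partition sum.
    """
    motifs = list(motifs)
    mirnas = sorted(
        {m.mirna for m in motifs}
        | ({normalize_mirna(m) for m in de_mirnas} if de_mirnas else set())
    )
    table = pd.DataFrame(0, index=mirnas, columns=list(MOTIF_KINDS))
    for inst in motifs:
        table.loc[inst.mirna, inst.kind] += 1
    table["total_ffl"] = table[["miRNA-FFL", "TF-FFL", "composite-FFL"]].sum(axis=1)
    table.loc["total"] = table.sum(axis=0)
    table.index.name = "mirna"
    return table


def motif_subgraph(motifs: Iterable[MotifInstance]) -> RegGraph:
    """Graph of motif-participating nodes and constituent edges only."""
    g = RegGraph()
    for inst in motifs:
        g.add_node(inst.tf, "TF")
        g.add_node(inst.mirna, "miRNA")
        if inst.gene is not None:
            g.add_node(inst.gene, "gene")
        for u, v in inst.edges:
            g.add_edge(u, v)
    return g


def degree_report(g: RegGraph, top_k: int = 5) -> pd.DataFrame:
    """Nodes ranked by total degree (incident unique directed edges, in + out).

    Ties are broken lexicographically; ``rank`` is 1-based position. Returns
    the full table with a ``hub`` flag on the top ``top_k`` rows.
    """
    rows = sorted(
        ((n, int(d)) for n, d in g.g.degree()), key=lambda nd: (-nd[1], nd[0])
    )
    df = pd.DataFrame(rows, columns=["node", "degree"])
    df["rank"] = range(1, len(df) + 1)
    df["hub"] = df["rank"] <= top_k
    return df


def common_regulators(tf_mirna: pd.DataFrame, mirnas: Iterable[str]) -> list[str]:
    """TFs with a TF -> miRNA edge to every listed miRNA (regulator-set intersection)."""
    wanted = [normalize_mirna(m) for m in mirnas]
    if not wanted:
        raise ValueError("At least one miRNA is required")
    by_mirna: dict[str, set[str]] = {}
    for _, r in tf_mirna.iterrows():
        by_mirna.setdefault(normalize_mirna(str(r["mirna"])), set()).add(str(r["tf"]))
    common = by_mirna.get(wanted[0], set()).copy()
    for m in wanted[1:]:
        common &= by_mirna.get(m, set())
    return sorted(common)


def core_members(
    motifs: Iterable[MotifInstance],
) -> tuple[list[str], list[str], list[str]]:
    """(genes, miRNAs, TFs) present in all three FFL subnetworks.

    An entity qualifies when it appears in at least one instance of each of
    miRNA-FFL, TF-FFL and composite-FFL.
    """
    per_kind: dict[str, dict[str, set[str]]] = {
        k: {"gene": set(), "mirna": set(), "tf": set()}
        for k in ("miRNA-FFL", "TF-FFL", "composite-FFL")
    }
    for inst in motifs:
        if inst.kind not in per_kind:
            continue
        per_kind[inst.kind]["tf"].add(inst.tf)
        per_kind[inst.kind]["mirna"].add(inst.mirna)
        if inst.gene is not None:
            per_kind[inst.kind]["gene"].add(inst.gene)
    kinds = list(per_kind.values())

    def inter(slot: str) -> list[str]:
        sets = [k[slot] for k in kinds]
        return sorted(set.intersection(*sets)) if sets else []

    return inter("gene"), inter("mirna"), inter("tf")


_SIF_TOKEN = {ACTIVATION: "activates", REPRESSION: "represses", UNKNOWN: "regulates"}


def export_network(g: RegGraph, path, fmt: str = "graphml") -> None:
    """Write the graph as GraphML, SIF or an edge TSV (Cytoscape-compatible).

    Node roles and edge signs travel as attributes in GraphML/TSV; SIF encodes
    the sign in the relation token (activates / represses / regulates).
    """
    fmt = fmt.lower()
    if g.n_nodes == 0:
        raise ValueError("Refusing to export an empty graph")
    if fmt == "graphml":
        h = nx.DiGraph()
        for n, d in g.g.nodes(data=True):
            h.add_node(n, roles="|".join(sorted(d["roles"])))
        for u, v, d in g.g.edges(data=True):
            h.add_edge(u, v, sign=d["sign"], provenance="|".join(sorted(d["provenance"])))
        nx.write_graphml(h, path)
    elif fmt == "sif":
        with open(path, "w") as fh:
            for u, v, d in sorted(g.g.edges(data=True)):
                fh.write(f"{u}\t{_SIF_TOKEN[d['sign']]}\t{v}\n")
    elif fmt in ("tsv", "edge-tsv"):
        rows = [
            {
                "source": u,
                "target": v,
                "sign": d["sign"],
                "source_roles": "|".join(sorted(g.roles(u))),
                "target_roles": "|".join(sorted(g.roles(v))),
                "provenance": "|".join(sorted(d["provenance"])),
            }
            for u, v, d in sorted(g.g.edges(data=True))
        ]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    else:
        raise ValueError(f"Unknown export format {fmt!r}")


def read_graphml(path) -> RegGraph:
    """Read back a GraphML file written by :func:`export_network`."""
    h = nx.read_graphml(path)
    g = RegGraph()
    for n, d in h.nodes(data=True):
        for role in str(d.get("roles", "gene")).split("|"):
            g.add_node(n, role)
    for u, v, d in h.edges(data=True):
        prov = str(d.get("provenance", ""))
        g.g.add_edge(
            u,
            v,
            sign=d.get("sign", UNKNOWN),
            provenance=set(p for p in prov.split("|") if p),
        )
    return g
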