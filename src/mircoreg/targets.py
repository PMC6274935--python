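"""Consensus integration of predicted and validated miRNA-target pairs.

Prediction tools (miRanda, RNA22, mirDB, TargetScan, DIANA-microT-CDS) have
low individual precision, so pairs are retained only when called by at least
``min_sources`` tools; validated pairs are kept when backed by reporter-gene
assays. The union of the two sets forms a bipartite miRNA -> gene network,
with a shared-target report describing which genes connect pairs of miRNAs.

File readers accept per-source TSV dialects (column-name mappings), either
from the built-in registry or from a YAML config.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd
import yaml

__all__ = [
    "PairProvenance",
    "PairSet",
    "MergeReport",
    "BipartiteSummary",
    "DIALECTS",
    "normalize_mirna",
    "normalize_gene",
    "read_pairs",
    "load_dialects",
    "consensus_filter",
    "merge_validated_predicted",
    "build_bipartite",
    "shared_targets",
]

#: Column mappings for the supported source export formats. Keys are lower-case
#: source names; values map the canonical fields (mirna, gene, evidence) to the
#: column headers used by that export.
DIALECTS: dict[str, dict[str, str]] = {
    "generic": {"mirna": "mirna", "gene": "gene", "evidence": "evidence"},
    "miranda": {"mirna": "mirna", "gene": "gene_symbol"},
    "rna22": {"mirna": "miRNA", "gene": "Gene"},
    "mirdb": {"mirna": "miRNA Name", "gene": "Gene Symbol"},
    "targetscan": {"mirna": "miRNA", "gene": "Gene Symbol"},
    "microt": {"mirna": "mirna", "gene": "gene"},
    "mirtarbase": {"mirna": "miRNA", "gene": "Target Gene", "evidence": "Experiments"},
    "tarbase": {"mirna": "mirna", "gene": "geneName", "evidence": "method"},
}

_MIR_PREFIX = re.compile(r"^(hsa-)?(mir|miR|MIR|let|LET)-?", re.IGNORECASE)


def normalize_mirna(name: str) -> str:
    """miRBase-style canonical form: lower-case family prefix, case kept for arms.

    ``HSA-MIR-320A`` -> ``miR-320a``; mature-arm suffixes (-5p/-3p) are
    preserved as significant.
    """
    name = name.strip()
    m = _MIR_PREFIX.match(name)
    if not m:
        return name
    rest = name[m.end():].lstrip("-")
    prefix = "let" if m.group(2).lower() == "let" else "miR"
    return f"{prefix}-{rest.lower()}"


def normalize_gene(symbol: str) -> str:
    return symbol.strip().upper()


@dataclass
class PairProvenance:
    predictors: set[str] = field(default_factory=set)
    validated: bool = False
    evidence: set[str] = field(default_factory=set)

    def merge(self, other: "PairProvenance") -> None:
        self.predictors |= other.predictors
        self.validated = self.validated or other.validated
        self.evidence |= other.evidence


class PairSet:
    """Set of (miRNA, gene) pairs with per-pair provenance.

    Pair identity is case-normalized; duplicate additions merge provenance.
    """

    def __init__(self):
        self._pairs: dict[tuple[str, str], PairProvenance] = {}

    def add(
        self,
        mirna: str,
        gene: str,
        predictor: str | None = None,
        validated: bool = False,
        evidence: str | None = None,
    ) -> None:
        key = (normalize_mirna(mirna), normalize_gene(gene))
        prov = self._pairs.setdefault(key, PairProvenance())
        if predictor is not None:
            prov.predictors.add(predictor)
        prov.validated = prov.validated or validated
        if evidence is not None:
            prov.evidence.add(evidence)

    def provenance(self, mirna: str, gene: str) -> PairProvenance:
        return self._pairs[(normalize_mirna(mirna), normalize_gene(gene))]

    def pairs(self) -> set[tuple[str, str]]:
        return set(self._pairs)

    def items(self):
        return self._pairs.items()

    def union(self, other: "PairSet") -> "PairSet":
        out = PairSet()
        for src in (self, other):
            for (m, g), prov in src.items():
                dst = out._pairs.setdefault((m, g), PairProvenance())
                dst.merge(prov)
        return out

    def __len__(self) -> int:
        return len(self._pairs)

    def __contains__(self, pair: tuple[str, str]) -> bool:
        m, g = pair
        return (normalize_mirna(m), normalize_gene(g)) in self._pairs

    def __eq__(self, other) -> bool:
        return isinstance(other, PairSet) and self.pairs() == other.pairs()

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "mirna": m,
                "gene": g,
                "predictors": "|".join(sorted(p.predictors)),
                "n_predictors": len(p.predictors),
                "validated": p.validated,
                "evidence": "|".join(sorted(p.evidence)),
            }
            for (m, g), p in sorted(self._pairs.items())
        ]
        return pd.DataFrame(
            rows,
            columns=["mirna", "gene", "predictors", "n_predictors", "validated", "evidence"],
        )

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "PairSet":
        ps = cls()
        for _, r in df.iterrows():
            preds = [p for p in str(r.get("predictors", "") or "").split("|") if p]
            evs = [e for e in str(r.get("evidence", "") or "").split("|") if e]
            key_added = False
            for p in preds:
                ps.add(r["mirna"], r["gene"], predictor=p)
                key_added = True
            for e in evs:
                ps.add(r["mirna"], r["gene"], evidence=e)
                key_added = True
            validated = bool(r.get("validated", False))
            if validated or not key_added:
                ps.add(r["mirna"], r["gene"], validated=validated)
        return ps

    @classmethod
    def read_tsv(cls, path) -> "PairSet":
        df = pd.read_csv(path, sep="\t", keep_default_na=False)
        if "validated" in df.columns:
            df["validated"] = df["validated"].astype(str).str.lower().isin(
                {"true", "1", "yes"}
            )
        return cls.from_frame(df)


def load_dialects(path) -> dict[str, dict[str, str]]:
    """Load per-source column mappings from a YAML file, overlaid on the registry."""
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    out = dict(DIALECTS)
    out.update({k.lower(): v for k, v in user.items()})
    return out


def read_pairs(
    path,
    source_name: str,
    dialect: dict[str, str] | None = None,
    validated: bool = False,
    evidence_filter: str | None = "reporter",
) -> PairSet:
    """Read one source's miRNA-target export into a normalized :class:`PairSet`.

    For validated sources, rows are kept only when the evidence column matches
    ``evidence_filter`` (substring, case-insensitive; default keeps
    reporter-gene-assay evidence). Prediction sources tag every pair with
    ``source_name`` as a predictor.
    """
    if dialect is None:
        try:
            dialect = DIALECTS[source_name.lower()]
        except KeyError:
            raise ValueError(
                f"Unknown source dialect {source_name!r}; pass an explicit column mapping"
            ) from None
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    for fld in ("mirna", "gene"):
        col = dialect[fld]
        if col not in df.columns:
            raise ValueError(
                f"Source {source_name!r}: required column {col!r} ({fld}) missing"
            )
    ev_col = dialect.get("evidence")
    if validated and ev_col is not None and ev_col not in df.columns:
        raise ValueError(
            f"Source {source_name!r}: evidence column {ev_col!r} missing"
        )
    ps = PairSet()
    for _, row in df.iterrows():
        evidence = str(row[ev_col]) if (ev_col and ev_col in df.columns) else None
        if validated:
            if evidence_filter is not None:
                if evidence is None or evidence_filter.lower() not in evidence.lower():
                    continue
            ps.add(row[dialect["mirna"]], row[dialect["gene"]],
                   validated=True, evidence=evidence)
        else:
            ps.add(row[dialect["mirna"]], row[dialect["gene"]], predictor=source_name)
    return ps


def consensus_filter(predicted: list[PairSet], min_sources: int = 4) -> PairSet:
    """Keep pairs predicted by at least ``min_sources`` of the supplied tools."""
    if min_sources > len(predicted):
        raise ValueError(
            f"min_sources={min_sources} exceeds the {len(predicted)} supplied sources"
        )
    merged = PairSet()
    for ps in predicted:
        merged = merged.union(ps)
    out = PairSet()
    for (m, g), prov in merged.items():
        if len(prov.predictors) >= min_sources:
            out._pairs[(m, g)] = PairProvenance(
                predictors=set(prov.predictors),
                validated=prov.validated,
                evidence=set(prov.evidence),
            )
    return out


@dataclass
class MergeReport:
    n_validated: int
    n_predicted: int
    n_overlap: int
    n_union: int


def merge_validated_predicted(
    validated: PairSet, predicted_consensus: PairSet
) -> tuple[PairSet, MergeReport]:
    """Union of validated and consensus-predicted pairs with overlap accounting.

    The union cardinality obeys inclusion-exclusion: |V| + |P| - |V ∩ P|.
    Overlapping pairs carry both provenance kinds.
    """
    union = validated.union(predicted_consensus)
    overlap = validated.pairs() & predicted_consensus.pairs()
    report = MergeReport(
        n_validated=len(validated),
        n_predicted=len(predicted_consensus),
        n_overlap=len(overlap),
        n_union=len(union),
    )
    assert report.n_union == report.n_validated + report.n_predicted - report.n_overlap
    return union, report


@dataclass
class BipartiteSummary:
    n_mirna: int
    n_gene: int
    n_nodes: int
    n_edges: int
    dropped_mirnas: list[str]


def shared_targets(pairs: PairSet) -> dict[tuple[str, str], set[str]]:
    """Genes targeted by both members of every miRNA pair (non-empty entries only)."""
    by_mirna: dict[str, set[str]] = {}
    for (m, g) in pairs.pairs():
        by_mirna.setdefault(m, set()).add(g)
    mirnas = sorted(by_mirna)
    out = {}
    for i, m1 in enumerate(mirnas):
        for m2 in mirnas[i + 1:]:
            common = by_mirna[m1] & by_mirna[m2]
            if common:
                out[(m1, m2)] = common
    return out


def build_bipartite(
    pairs: PairSet, drop_isolated_mirnas: bool = False
) -> tuple[nx.DiGraph, dict[tuple[str, str], set[str]], BipartiteSummary]:
    """Directed bipartite miRNA -> gene network with a shared-target report.

    With ``drop_isolated_mirnas``, miRNAs sharing no target with any other
    miRNA are excluded from the exported network (they remain in the summary's
    ``dropped_mirnas`` list).
    """
    if len(pairs) == 0:
        raise ValueError("Empty pair set")
    shared = shared_targets(pairs)
    mirnas = sorted({m for (m, _) in pairs.pairs()})
    connected = {m for pair in shared for m in pair}
    dropped = [m for m in mirnas if m not in connected] if drop_isolated_mirnas else []
    keep = set(mirnas) - set(dropped)

    g = nx.DiGraph()
    for (m, gene), prov in sorted(pairs.items()):
        if m not in keep:
            continue
        g.add_node(m, node_type="miRNA")
        g.add_node(gene, node_type="gene")
        g.add_edge(
            m,
            gene,
            predictors="|".join(sorted(prov.predictors)),
            validated=prov.validated,
        )
    n_mirna = sum(1 for _, d in g.nodes(data=True) if d["node_type"] == "miRNA")
    n_gene = g.number_of_nodes() - n_mirna
    summary = BipartiteSummary(
        n_mirna=n_mirna,
        n_gene=n_gene,
        n_nodes=g.number_of_nodes(),
        n_edges=g.number_of_edges(),
        dropped_mirnas=dropped,
    )
    return g, shared, summary
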