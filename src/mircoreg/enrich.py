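"""Hypergeometric over-representation analysis against GMT gene-set collections.

For a query gene list drawn from a background universe, each term's overlap
is scored with the hypergeometric upper tail P(X >= k) and the resulting
p-values are Benjamini-Hochberg adjusted across all tested terms.
"""

from __future__ import annotations

import warnings

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .targets import normalize_gene

__all__ = ["read_gmt", "write_gmt", "hypergeom_upper", "enrich"]


def read_gmt(path) -> dict[str, tuple[str, set[str]]]:
    """Parse a GMT file into {term_id: (description, gene set)}.

    GMT is tab-separated: term id, description, then one gene per field.
    Gene symbols are case-normalized.
    """
    sets: dict[str, tuple[str, set[str]]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"Malformed GMT line (needs >= 3 fields): {line[:80]!r}")
            term, desc = fields[0], fields[1]
            sets[term] = (desc, {normalize_gene(g) for g in fields[2:] if g})
    return sets


def write_gmt(gene_sets: dict[str, tuple[str, set[str]]], path) -> None:
    with open(path, "w") as fh:
        for term, (desc, genes) in gene_sets.items():
            fh.write("\t".join([term, desc, *sorted(genes)]) + "\n")


def hypergeom_upper(
    overlap: int, query_size: int, term_size: int, background_size: int
) -> float:
    """P(X >= overlap) for X ~ Hypergeom(background, term, query draws)."""
    if not (0 <= overlap <= min(query_size, term_size)):
        raise ValueError(
            f"overlap={overlap} inconsistent with query={query_size}, term={term_size}"
        )
    if term_size > background_size or query_size > background_size:
        raise ValueError("term and query sizes cannot exceed the background size")
    return float(hypergeom.sf(overlap - 1, background_size, term_size, query_size))


def enrich(
    query,
    gene_sets: dict[str, tuple[str, set[str]]],
    background=None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Over-representation of ``query`` genes in each gene set.

    ``background`` defaults to the union of all genes in the collection.
    Query genes outside the background are dropped with a warning. Returns one
    row per term with non-zero overlap, BH-adjusted and sorted by adjusted p
    (ties by raw p then term id), with ``significant`` flagged at
    p_adj < ``alpha``.
    """
    if not gene_sets:
        raise ValueError("Empty gene-set collection")
    query = {normalize_gene(g) for g in query}
    if not query:
        raise ValueError("Empty query gene list")
    if background is None:
        background = set().union(*(genes for _, genes in gene_sets.values()))
    else:
        background = {normalize_gene(g) for g in background}
    outside = query - background
    if outside:
        warnings.warn(
            f"Dropped {len(outside)} query gene(s) absent from the background",
            stacklevel=2,
        )
        query -= outside
    if not query:
        raise ValueError("No query genes remain within the background")

    n_bg, n_q = len(background), len(query)
    rows = []
    for term, (desc, genes) in gene_sets.items():
        genes_bg = genes & background
        hits = sorted(query & genes_bg)
        if not hits:
            continue
        p = hypergeom_upper(len(hits), n_q, len(genes_bg), n_bg)
        rows.append(
            {
                "term_id": term,
                "term_name": desc,
                "overlap_count": len(hits),
                "term_size": len(genes_bg),
                "query_size": n_q,
                "background_size": n_bg,
                "p_raw": p,
                "overlapping_gene_ids": "|".join(hits),
            }
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "term_id", "term_name", "overlap_count", "term_size",
            "query_size", "background_size", "p_raw", "overlapping_gene_ids",
        ],
    )
    if df.empty:
        df["p_adj"] = []
        df["significant"] = []
        return df
    df["p_adj"] = multipletests(df["p_raw"], method="fdr_bh")[1]
    df["significant"] = df["p_adj"] < alpha
    df = df.sort_values(
        ["p_adj", "p_raw", "term_id"], kind="mergesort"
    ).reset_index(drop=True)
    return df
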