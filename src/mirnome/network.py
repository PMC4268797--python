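"""miRNA-target bipartite network summaries and gene-set over-representation.

Builds the bipartite graph of experimentally supported miRNA-target edges
restricted to a query marker set, reports hub targets (genes hit by many
query miRNAs), and tests the targeted genes for over-representation in
user-supplied gene sets (GMT) with an upper-tail hypergeometric test,
BH-adjusted across sets.
"""

from __future__ import annotations

from typing import Callable, Iterable, Mapping

import networkx as nx
import pandas as pd
from scipy.stats import hypergeom

from .diffexp import benjamini_hochberg
from .errors import InputError

__all__ = ["build_graph", "hub_targets", "targeted_genes", "ora_hypergeometric",
           "graph_to_edges"]


def build_graph(
    interactions: pd.DataFrame,
    mirna_query: Iterable[str],
    evidence_filter: str | Iterable[str] | Callable[[str], bool] | None = None,
) -> nx.Graph:
    """Bipartite graph of interactions whose miRNA is in the query set.

    ``interactions`` needs columns mirna_id, gene_id, evidence.  Duplicate
    (miRNA, gene) pairs collapse to one edge.  ``evidence_filter`` may be a
    single tag (e.g. ``"reporter_assay"``), a collection of tags, or a
    predicate on the tag.  An empty query yields an empty graph.
    """
    required = {"mirna_id", "gene_id", "evidence"}
    if not required.issubset(interactions.columns):
        raise InputError(f"interaction table needs columns {sorted(required)}")
    query = set(mirna_query)
    df = interactions[interactions["mirna_id"].isin(query)]
    if evidence_filter is not None:
        if callable(evidence_filter):
            keep = df["evidence"].map(evidence_filter).astype(bool)
        elif isinstance(evidence_filter, str):
            keep = df["evidence"] == evidence_filter
        else:
            keep = df["evidence"].isin(set(evidence_filter))
        df = df[keep]
    df = df.drop_duplicates(subset=["mirna_id", "gene_id"])
    g = nx.Graph()
    g.add_nodes_from(query, bipartite="mirna")
    for m, t in zip(df["mirna_id"], df["gene_id"]):
        g.add_node(m, bipartite="mirna")
        g.add_node(t, bipartite="gene")
        g.add_edge(m, t)
    return g


def targeted_genes(graph: nx.Graph) -> set[str]:
    return {n for n, d in graph.nodes(data=True) if d.get("bipartite") == "gene"}


def hub_targets(graph: nx.Graph, k: int) -> pd.DataFrame:
    """Genes targeted by at least ``k`` distinct query miRNAs.

    Sorted by degree descending, gene id ascending.
    """
    if k < 1:
        raise InputError("k must be >= 1")
    rows = [
        {"gene_id": n, "degree": graph.degree(n)}
        for n in targeted_genes(graph)
        if graph.degree(n) >= k
    ]
    return (
        pd.DataFrame(rows, columns=["gene_id", "degree"])
        .sort_values(["degree", "gene_id"], ascending=[False, True], ignore_index=True)
        .astype({"degree": int})
    )


def ora_hypergeometric(
    query_genes: Iterable[str],
    gene_sets: Mapping[str, Iterable[str]],
    universe: Iterable[str],
) -> pd.DataFrame:
    """Upper-tail hypergeometric over-representation of ``query_genes`` per set.

    P(overlap >= observed) drawing ``|query|`` genes from ``|universe|`` of
    which ``|set ∩ universe|`` are in the set.  Sets are intersected with the
    universe first; the query must be a subset of the universe.  BH adjustment
    across the tested sets.
    """
    uni = set(universe)
    if not uni:
        raise InputError("universe is empty")
    query = set(query_genes)
    stray = query - uni
    if stray:
        raise InputError(f"query genes outside universe: {sorted(stray)[:5]}")
    rows = []
    for name, members in gene_sets.items():
        inset = set(members) & uni
        k = len(query & inset)
        p = float(hypergeom.sf(k - 1, len(uni), len(inset), len(query)))
        rows.append(
            {
                "set_name": name,
                "overlap_count": k,
                "set_size": len(inset),
                "query_size": len(query),
                "universe_size": len(uni),
                "p_raw": min(max(p, 5e-324), 1.0),
            }
        )
    out = pd.DataFrame(rows)
    if not out.empty:
        out["p_adjusted"] = benjamini_hochberg(out["p_raw"].clip(lower=1e-300))
    return out


def graph_to_edges(graph: nx.Graph) -> pd.DataFrame:
    """Edge table (mirna_id, gene_id) of a bipartite miRNA-target graph."""
    rows = []
    for u, v in graph.edges():
        if graph.nodes[u].get("bipartite") == "mirna":
            rows.append({"mirna_id": u, "gene_id": v})
        else:
            rows.append({"mirna_id": v, "gene_id": u})
    return pd.DataFrame(rows, columns=["mirna_id", "gene_id"]).sort_values(
        ["mirna_id", "gene_id"], ignore_index=True
    )
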