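"""Enriched-pathway overlap networks and between-model comparison.

Nodes are pathways passing the enrichment P threshold, annotated with
the number of pathway genes regulated by the signature's targets and a
categorical significance tier; edges connect pathway pairs whose
regulated gene sets overlap, weighted by the Jaccard index.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import pandas as pd

from .enrichment import PathwayDB, significance_tier
from .errors import ContractError

__all__ = ["jaccard", "build_network", "compare_networks", "GeneSetComparison"]


def jaccard(set_a, set_b) -> float:
    """|A n B| / |A u B|; 0 when both sets are empty."""
    a, b = set(set_a), set(set_b)
    union = a | b
    if not union:
        return 0.0
    return len(a & b) / len(union)


@dataclass
class GeneSetComparison:
    """Partition of two networks' pooled regulated-gene sets.

    ``frequency`` counts, per gene of the union, the number of pathway
    nodes (across both networks) whose regulated gene set contains it,
    sorted descending.
    """

    specific_a: frozenset
    shared: frozenset
    specific_b: frozenset
    frequency: pd.Series

    def sizes(self) -> tuple[int, int, int]:
        return len(self.specific_a), len(self.shared), len(self.specific_b)


def build_network(
    enrichment: pd.DataFrame,
    db: PathwayDB,
    regulated_genes,
    p_threshold: float = 0.05,
    p_column: str = "fisher_p",
    full_membership: bool = False,
) -> nx.Graph:
    """Pathway-overlap graph of pathways enriched below ``p_threshold``.

    ``regulated_genes`` is the targeted gene set of the same signature
    the enrichment was run on.  Node attributes: ``regulated`` (sorted
    tuple of pathway genes hit by the signature), ``count``, ``p``,
    ``tier``.  Edges carry the Jaccard ``weight`` of the two nodes'
    regulated gene sets (full pathway memberships instead when
    ``full_membership``); zero-overlap pairs get no edge.
    """
    if p_column not in enrichment.columns:
        raise ContractError(f"enrichment table has no column {p_column!r}")
    regulated = set(regulated_genes)
    passing = enrichment.index[enrichment[p_column] < p_threshold]
    g = nx.Graph()
    if len(passing) == 0:
        warnings.warn("no pathway passes the enrichment threshold; empty network")
    for name in passing:
        members = db.pathways[name]
        reg = tuple(sorted(members & regulated))
        p = float(enrichment.at[name, p_column])
        g.add_node(name, regulated=reg, count=len(reg), p=p, tier=significance_tier(p))
    nodes = sorted(g.nodes)
    for i, u in enumerate(nodes):
        su = set(db.pathways[u]) if full_membership else set(g.nodes[u]["regulated"])
        for v in nodes[i + 1 :]:
            sv = set(db.pathways[v]) if full_membership else set(g.nodes[v]["regulated"])
            w = jaccard(su, sv)
            if w > 0:
                g.add_edge(u, v, weight=w)
    return g


def _pooled_regulated(net: nx.Graph) -> set:
    pooled: set = set()
    for _, data in net.nodes(data=True):
        pooled |= set(data["regulated"])
    return pooled


def compare_networks(net_a: nx.Graph, net_b: nx.Graph) -> GeneSetComparison:
    """Exclusive/shared partition of the two pooled regulated gene sets,
    plus the per-gene pathway-frequency ranking over both networks."""
    pool_a = _pooled_regulated(net_a)
    pool_b = _pooled_regulated(net_b)
    union = pool_a | pool_b
    freq = {}
    for gene in union:
        count = 0
        for net in (net_a, net_b):
            for _, data in net.nodes(data=True):
                if gene in data["regulated"]:
                    count += 1
        freq[gene] = count
    frequency = pd.Series(freq, dtype=int).sort_values(ascending=False, kind="stable")
    return GeneSetComparison(
        specific_a=frozenset(pool_a - pool_b),
        shared=frozenset(pool_a & pool_b),
        specific_b=frozenset(pool_b - pool_a),
        frequency=frequency,
    )
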