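"""Hypergeometric gene-set enrichment and enrichment-map construction.

For a query of n genes drawn from a universe of N genes, a term with K
members inside the universe and k members inside the query gets the exact
upper-tail hypergeometric p-value P[X >= k]; BH correction runs over all
tested terms. The enrichment map connects significant terms (q <= cutoff)
whenever the Jaccard similarity of their universe-restricted memberships
reaches the edge threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
import scipy.stats

from .diffexpr import bh_fdr
from .io_formats import GeneSetCollection


@dataclass
class EnrichmentResult:
    """Per-term enrichment table plus the universe-restricted memberships."""

    table: pd.DataFrame  # index term_id; columns name, k, K, n, N, p, q
    memberships: dict[str, frozenset[str]]

    def significant(self, q_cutoff: float) -> list[str]:
        return list(self.table.index[self.table["q"] <= q_cutoff])


def hypergeom_enrich(query: set[str], universe: set[str],
                     collection: GeneSetCollection) -> EnrichmentResult:
    """Exact upper-tail hypergeometric enrichment over a gene-set collection.

    Term memberships are intersected with the universe before testing; terms
    with no member in the universe are skipped rather than scored. Raises if
    the query is not contained in the universe.
    """
    offenders = sorted(set(query) - set(universe))
    if offenders:
        raise ValueError(
            f"query genes outside the universe: {offenders[:10]}"
            + ("..." if len(offenders) > 10 else "")
        )
    n = len(query)
    bigN = len(universe)
    rows = []
    memberships: dict[str, frozenset[str]] = {}
    for term in collection:
        members = term.genes & universe
        bigK = len(members)
        if bigK == 0:
            continue
        k = len(members & query)
        # P[X >= k], X ~ Hypergeom(N, K, n)
        p = float(scipy.stats.hypergeom.sf(k - 1, bigN, bigK, n))
        p = min(max(p, np.nextafter(0, 1)), 1.0)
        rows.append((term.term_id, term.name, k, bigK, n, bigN, p))
        memberships[term.term_id] = frozenset(members)
    table = pd.DataFrame(
        rows, columns=["term_id", "name", "k", "K", "n", "N", "p"]
    ).set_index("term_id")
    table["q"] = bh_fdr(table["p"].to_numpy()) if len(table) else []
    return EnrichmentResult(table=table, memberships=memberships)


def jaccard(a: frozenset[str], b: frozenset[str]) -> float:
    union = a | b
    if not union:
        return 0.0
    return len(a & b) / len(union)


def enrichment_map(result: EnrichmentResult,
                   jaccard_min: float = 0.25,
                   q_cutoff: float = 0.025) -> nx.Graph:
    """Network of significant terms with Jaccard-overlap edges.

    Nodes are terms with q <= ``q_cutoff`` (attributes: name, q, k); an edge
    joins two terms when the Jaccard similarity of their universe-restricted
    memberships is at least ``jaccard_min``.
    """
    g = nx.Graph(jaccard_min=jaccard_min, q_cutoff=q_cutoff)
    sig = result.significant(q_cutoff)
    for t in sig:
        row = result.table.loc[t]
        g.add_node(t, name=row["name"], q=float(row["q"]), k=int(row["k"]))
    for i, a in enumerate(sig):
        for b in sig[i + 1:]:
            j = jaccard(result.memberships[a], result.memberships[b])
            if j >= jaccard_min:
                g.add_edge(a, b, jaccard=j)
    return g
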