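"""Guilt-by-association functional annotation.

A lncRNA with unknown function inherits the functions statistically enriched
among its perfectly co-expressed protein-coding genes. Enrichment of a query
gene list against a GMT collection uses the upper-tail (cumulative)
hypergeometric test with a configurable universe, BH correction across sets,
and two reported filters: -log10(p) above a threshold (6 by default) and
q <= 0.05. Significant terms are related to each other by Cohen's kappa
between their binary gene-membership vectors over the union of significant-
term genes; kappa > 0.3 draws an edge and connected components form term
clusters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .data_model import GeneSetCollection
from .network import CoexpressionNetwork

logger = logging.getLogger("lncnet")


@dataclass
class EnrichmentResult:
    table: pd.DataFrame        # per set: overlap, sizes, p, q, neg_log10_p, filters
    universe_size: int
    query_size: int
    dropped_from_universe: list[str]

    def significant(self, by: str = "neg_log10_p") -> pd.DataFrame:
        col = {"neg_log10_p": "passes_logp", "q": "passes_q"}[by]
        return self.table[self.table[col]]


def hypergeom_enrich(
    query_genes,
    sets: GeneSetCollection,
    universe,
    logp_threshold: float = 6.0,
    q_max: float = 0.05,
) -> EnrichmentResult:
    """Upper-tail hypergeometric enrichment of a query list against gene sets.

    Query genes absent from the universe are dropped and reported (the
    enrichment background must contain every tested gene). Set members are
    intersected with the universe before testing.
    """
    uni = list(dict.fromkeys(universe))
    if not uni:
        raise ValueError("empty universe")
    uni_set = set(uni)
    query = list(dict.fromkeys(query_genes))
    dropped = [g for g in query if g not in uni_set]
    if dropped:
        logger.info("hypergeom_enrich: dropped %d query genes absent from universe", len(dropped))
    query_set = set(query) - set(dropped)
    m = len(uni_set)
    n_query = len(query_set)
    rows = []
    for sid, (name, members) in sets.sets.items():
        term = set(members) & uni_set
        k = len(term & query_set)
        # P(X >= k), X ~ Hypergeom(M=m, K=|term|, N=n_query)
        p = float(stats.hypergeom.sf(k - 1, m, len(term), n_query)) if term else 1.0
        rows.append(
            {
                "set_id": sid,
                "name": name,
                "overlap": k,
                "query_size": n_query,
                "term_size": len(term),
                "universe_size": m,
                "p": min(max(p, 0.0), 1.0),
                "members_in_overlap": sorted(term & query_set),
            }
        )
    table = pd.DataFrame(rows)
    if len(table):
        table["q"] = multipletests(table["p"], method="fdr_bh")[1]
        with np.errstate(divide="ignore"):
            table["neg_log10_p"] = -np.log10(table["p"])
        table["passes_logp"] = table["neg_log10_p"] > logp_threshold
        table["passes_q"] = table["q"] <= q_max
        table = table.sort_values("p").reset_index(drop=True)
    return EnrichmentResult(
        table=table,
        universe_size=m,
        query_size=n_query,
        dropped_from_universe=dropped,
    )


def cohen_kappa(a: np.ndarray, b: np.ndarray) -> float:
    """Cohen's kappa between two binary membership vectors."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    n = len(a)
    po = float((a == b).mean())
    pa, pb = a.mean(), b.mean()
    pe = pa * pb + (1 - pa) * (1 - pb)
    if pe == 1.0:
        return 1.0
    return (po - pe) / (1.0 - pe)


def kappa_term_graph(
    result: EnrichmentResult,
    sets: GeneSetCollection,
    kappa_min: float = 0.3,
    by: str = "neg_log10_p",
) -> nx.Graph:
    """Kappa-similarity graph over significant terms.

    Membership vectors are taken over the union of the significant terms'
    genes; edges appear where kappa exceeds ``kappa_min``, and connected
    components are the term clusters (stored as the ``cluster`` node
    attribute).
    """
    sig = result.significant(by=by)
    term_ids = list(sig["set_id"])
    g = nx.Graph()
    g.add_nodes_from(term_ids)
    if len(term_ids) < 2:
        for node in g.nodes:
            g.nodes[node]["cluster"] = 0
        return g
    gene_union = sorted(set().union(*(set(sets.members(t)) for t in term_ids)))
    idx = {gene: i for i, gene in enumerate(gene_union)}
    vectors = {}
    for t in term_ids:
        v = np.zeros(len(gene_union), dtype=bool)
        for gene in sets.members(t):
            if gene in idx:
                v[idx[gene]] = True
        vectors[t] = v
    for i, a in enumerate(term_ids):
        for b in term_ids[i + 1:]:
            kap = cohen_kappa(vectors[a], vectors[b])
            if kap > kappa_min:
                g.add_edge(a, b, kappa=kap)
    for ci, comp in enumerate(sorted(nx.connected_components(g), key=lambda c: sorted(c))):
        for node in comp:
            g.nodes[node]["cluster"] = ci
    return g


def assign_lnc_functions(
    net: CoexpressionNetwork,
    sets: GeneSetCollection,
    universe,
    disease_set_ids=(),
    logp_threshold: float = 6.0,
    q_max: float = 0.05,
) -> pd.DataFrame:
    """Per-lncRNA functional assignment from its co-expressed mRNA set.

    For each lncRNA in the network: enrich its mRNA neighbour set, keep
    terms passing either filter, record which disease sets contain at least
    one of its mRNAs, and tabulate how many of its mRNAs are unique to it
    versus shared with other lncRNAs (the overlap statistics a Circos plot
    would draw), including the list of overlap partners.
    """
    disease_set_ids = list(disease_set_ids)
    unknown = [d for d in disease_set_ids if d not in sets.sets]
    if unknown:
        raise ValueError(f"disease sets not in collection: {unknown}")
    nbrs = net.neighbours()
    mrna_owner: dict[str, set[str]] = {}
    for ln, ns in nbrs.items():
        for m in ns:
            mrna_owner.setdefault(m, set()).add(ln)
    rows = []
    for ln in sorted(nbrs):
        ns = nbrs[ln]
        if not ns:
            rows.append({"lncrna": ln, "n_mrna": 0})
            continue
        enr = hypergeom_enrich(sorted(ns), sets, universe, logp_threshold, q_max)
        assigned = sorted(
            set(enr.significant("neg_log10_p")["set_id"]) | set(enr.significant("q")["set_id"])
        )
        memberships = sorted(
            d for d in disease_set_ids if ns & set(sets.members(d))
        )
        shared = {m for m in ns if len(mrna_owner[m]) > 1}
        partners = sorted(
            set().union(*(mrna_owner[m] for m in shared)) - {ln} if shared else set()
        )
        rows.append(
            {
                "lncrna": ln,
                "n_mrna": len(ns),
                "assigned_terms": assigned,
                "disease_memberships": memberships,
                "n_mrna_shared": len(shared),
                "n_mrna_unique": len(ns) - len(shared),
                "overlap_partners": partners,
            }
        )
    return pd.DataFrame(rows).set_index("lncrna")
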