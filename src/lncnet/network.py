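"""Perfect-correlation bipartite lncRNA-mRNA co-expression network.

Every candidate lncRNA is tested against every differentially expressed
protein-coding gene with the exact small-sample Spearman test on the
upper-quartile-normalized values. An edge is retained when |rho| reaches
``rho_min`` (1.0 by default, within a 1e-12 tolerance — both signs, with a
``positive_only`` switch) and the exact two-sided p-value is below
``p_max`` (0.005). Retained pairs whose gene loci overlap on the same
chromosome (strand-agnostic, any shared base) are excluded and logged: a
perfectly correlated overlapping pair is more parsimoniously explained by
shared locus artefacts than by regulation.

lncRNA clusters are the connected components of the lncRNA-lncRNA graph
that links two lncRNAs when they share at least one co-expressed mRNA;
lncRNAs sharing no mRNA with anyone are reported as acting alone. Groups
with *identical* mRNA neighbour sets are reported separately.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .data_model import CountMatrix, GeneAnnotation
from .spearman import ConstantInputError, RHO_TOL, spearman_exact

logger = logging.getLogger("lncnet")

EDGE_COLUMNS = ["lncrna", "mrna", "rho", "p", "overlap_excluded", "direction_consistent"]


@dataclass
class CoexpressionNetwork:
    """Retained bipartite edges plus exclusion log and cluster structure."""

    edges: pd.DataFrame                  # retained edges only
    excluded: pd.DataFrame               # overlap-excluded perfect pairs
    skipped_pairs: list[tuple[str, str]] # constant-vector pairs
    n_pairs_tested: int = 0
    lnc_clusters: list[dict] | None = None

    def graph(self) -> nx.Graph:
        g = nx.Graph()
        for _, row in self.edges.iterrows():
            g.add_node(row["lncrna"], bipartite="lncrna", kind="lncRNA")
            g.add_node(row["mrna"], bipartite="mrna", kind="mRNA")
            g.add_edge(row["lncrna"], row["mrna"], rho=float(row["rho"]), p=float(row["p"]))
        return g

    def neighbours(self) -> dict[str, set[str]]:
        out: dict[str, set[str]] = {}
        for _, row in self.edges.iterrows():
            out.setdefault(row["lncrna"], set()).add(row["mrna"])
        return out

    def degree_census(self) -> dict:
        deg_lnc = self.edges["lncrna"].value_counts()
        deg_mrna = self.edges["mrna"].value_counts()
        return {
            "n_lnc": int(deg_lnc.size),
            "n_mrna": int(deg_mrna.size),
            "n_edges": int(len(self.edges)),
            "min_lnc_degree": int(deg_lnc.min()) if len(deg_lnc) else 0,
        }


def _intervals_overlap(a, b) -> bool:
    return a["chrom"] == b["chrom"] and a["start"] <= b["end"] and b["start"] <= a["end"]


def build_network(
    cm_uqua: CountMatrix,
    candidate_lnc_ids,
    de_pcg_ids,
    ann: GeneAnnotation,
    de_table: pd.DataFrame | None = None,
    rho_min: float = 1.0,
    p_max: float = 0.005,
    positive_only: bool = False,
    mc_seed: int = 0,
) -> CoexpressionNetwork:
    """Test all candidate-lncRNA x DE-PCG pairs and keep perfect edges."""
    values = cm_uqua.values
    lncs = [g for g in candidate_lnc_ids if g in values.index]
    mrnas = [g for g in de_pcg_ids if g in values.index]
    iv = ann.intervals()
    retained, excluded, skipped = [], [], []
    n_tested = 0
    for ln in lncs:
        x = values.loc[ln].to_numpy(float)
        for mr in mrnas:
            if ln == mr:
                continue
            n_tested += 1
            y = values.loc[mr].to_numpy(float)
            try:
                rho, p = spearman_exact(x, y, seed=mc_seed)
            except ConstantInputError:
                skipped.append((ln, mr))
                continue
            if abs(rho) < rho_min - RHO_TOL or p >= p_max:
                continue
            if positive_only and rho < 0:
                continue
            overlap = False
            if ln in iv.index and mr in iv.index:
                overlap = _intervals_overlap(iv.loc[ln], iv.loc[mr])
            consistent = None
            if de_table is not None and ln in de_table.index and mr in de_table.index:
                consistent = bool(
                    np.sign(de_table.at[ln, "log2fc"]) == np.sign(de_table.at[mr, "log2fc"])
                )
            rec = {
                "lncrna": ln,
                "mrna": mr,
                "rho": rho,
                "p": p,
                "overlap_excluded": overlap,
                "direction_consistent": consistent,
            }
            (excluded if overlap else retained).append(rec)
    edges = pd.DataFrame(retained, columns=EDGE_COLUMNS)
    excl = pd.DataFrame(excluded, columns=EDGE_COLUMNS)
    if len(excl):
        logger.info("build_network: excluded %d genomically overlapping perfect pairs", len(excl))
    logger.info(
        "build_network: %d pairs tested, %d edges retained (%d lncRNAs, %d mRNAs)",
        n_tested, len(edges), edges["lncrna"].nunique(), edges["mrna"].nunique(),
    )
    if len(skipped):
        logger.info("build_network: %d pairs skipped (constant vector)", len(skipped))
    return CoexpressionNetwork(
        edges=edges, excluded=excl, skipped_pairs=skipped, n_pairs_tested=n_tested
    )


def cluster_lncrnas(net: CoexpressionNetwork) -> list[dict]:
    """Group lncRNAs that share co-expressed mRNAs.

    Primary grouping: connected components of the lncRNA-lncRNA graph with
    an edge whenever two lncRNAs share >= 1 mRNA. Also reports exact-set
    groups (identical neighbour sets) and flags singletons acting alone.
    """
    nbrs = net.neighbours()
    g = nx.Graph()
    g.add_nodes_from(nbrs)
    lnc_list = list(nbrs)
    for i, a in enumerate(lnc_list):
        for b in lnc_list[i + 1:]:
            if nbrs[a] & nbrs[b]:
                g.add_edge(a, b)
    exact: dict[frozenset, list[str]] = {}
    for ln, ns in nbrs.items():
        exact.setdefault(frozenset(ns), []).append(ln)
    exact_group_of = {ln: i for i, (_, members) in enumerate(sorted(exact.items(), key=lambda kv: sorted(kv[1]))) for ln in members}
    clusters = []
    for comp in sorted(nx.connected_components(g), key=lambda c: sorted(c)):
        members = sorted(comp)
        clusters.append(
            {
                "members": members,
                "n_lnc": len(members),
                "mrnas": sorted(set().union(*(nbrs[m] for m in members))),
                "acting_alone": len(members) == 1,
                "exact_groups": sorted({exact_group_of[m] for m in members}),
            }
        )
    net.lnc_clusters = clusters
    return clusters


def pathway_subnetwork(
    net: CoexpressionNetwork, gene_set_members, de_table: pd.DataFrame | None = None
) -> dict:
    """Census of the subnetwork induced by one pathway's mRNAs."""
    members = set(gene_set_members)
    sub = net.edges[net.edges["mrna"].isin(members)]
    census = {
        "n_lnc": int(sub["lncrna"].nunique()),
        "n_mrna": int(sub["mrna"].nunique()),
        "n_edges": int(len(sub)),
    }
    if de_table is not None:
        direction = {}
        for g in set(sub["lncrna"]) | set(sub["mrna"]):
            direction[g] = de_table.at[g, "status"] if g in de_table.index else "unknown"
        census["node_direction"] = direction
    census["edges"] = sub[["lncrna", "mrna", "rho"]].to_dict(orient="records")
    return census
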