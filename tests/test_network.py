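import numpy as np
import pandas as pd
import pytest

from lncnet.data_model import CountMatrix, GeneAnnotation
from lncnet.network import (
    CoexpressionNetwork,
    build_network,
    cluster_lncrnas,
    pathway_subnetwork,
)
from lncnet.spearman import exact_null_distribution


def _ann(rows):
    return GeneAnnotation(pd.DataFrame(
        rows, columns=["gene_id", "symbol", "biotype", "chrom", "start", "end", "strand"]
    ))


def _uqua(values_dict, groups=("healthy",) * 3 + ("tumour",) * 3):
    samples = [f"S{i + 1}" for i in range(6)]
    df = pd.DataFrame(values_dict, index=samples).T
    df.columns = samples
    return CountMatrix(df.astype(float), pd.Series(list(groups), index=samples), "uqua")


@pytest.fixture
def toy_net():
    order = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
    cm = _uqua({
        "lnc1": order * 10,
        "m1": order * 3,
        "m2": order + 100,
        "m3": order[::-1] * 7,          # reversed: rho = -1
        "m4": [1, 2, 3, 4, 6, 5],       # one swap: not perfect
    })
    ann = _ann([
        ("lnc1", "L1", "lincRNA", "chr1", 1000, 2000, "+"),
        ("m1", "M1", "protein_coding", "chr1", 5000, 6000, "+"),
        ("m2", "M2", "protein_coding", "chr2", 1000, 2000, "-"),
        ("m3", "M3", "protein_coding", "chr3", 1000, 2000, "+"),
        ("m4", "M4", "protein_coding", "chr4", 1000, 2000, "+"),
    ])
    return cm, ann


class TestBuildNetwork:
    def test_perfect_pairs_retained_both_signs(self, toy_net):
        cm, ann = toy_net
        net = build_network(cm, ["lnc1"], ["m1", "m2", "m3", "m4"], ann)
        got = {(r.lncrna, r.mrna): r.rho for r in net.edges.itertuples()}
        assert set(got) == {("lnc1", "m1"), ("lnc1", "m2"), ("lnc1", "m3")}
        assert got[("lnc1", "m3")] == pytest.approx(-1.0)

    def test_positive_only_switch_drops_negative_edges(self, toy_net):
        cm, ann = toy_net
        net = build_network(cm, ["lnc1"], ["m1", "m2", "m3"], ann, positive_only=True)
        assert set(net.edges["mrna"]) == {"m1", "m2"}

    def test_overlapping_pair_excluded_and_logged(self, toy_net):
        cm, _ = toy_net
        ann = _ann([
            ("lnc1", "L1", "lincRNA", "chr1", 100, 200, "+"),
            ("m1", "M1", "protein_coding", "chr1", 150, 300, "-"),
        ])
        net = build_network(cm, ["lnc1"], ["m1"], ann)
        assert len(net.edges) == 0
        assert len(net.excluded) == 1
        assert net.excluded.iloc[0]["overlap_excluded"]

    def test_only_perfect_rho_survives_default_cutoff_at_n6(self):
        rho, counts = exact_null_distribution(6)
        n_fact = counts.sum()
        for r in np.unique(np.abs(rho)):
            p = counts[np.abs(rho) >= r - 1e-12].sum() / n_fact
            if p < 0.005:
                assert r == pytest.approx(1.0)

    def test_relaxing_thresholds_never_removes_edges(self, toy_net):
        cm, ann = toy_net
        strict = build_network(cm, ["lnc1"], ["m1", "m2", "m3", "m4"], ann)
        loose = build_network(cm, ["lnc1"], ["m1", "m2", "m3", "m4"], ann,
                              rho_min=0.9, p_max=0.02)
        strict_set = set(map(tuple, strict.edges[["lncrna", "mrna"]].to_numpy()))
        loose_set = set(map(tuple, loose.edges[["lncrna", "mrna"]].to_numpy()))
        assert strict_set <= loose_set
        assert ("lnc1", "m4") in loose_set

    def test_network_is_bipartite(self, default_run):
        _, report = default_run
        g = report.network.graph()
        lnc = {n for n, d in g.nodes(data=True) if d["kind"] == "lncRNA"}
        for a, b in g.edges():
            assert (a in lnc) != (b in lnc)
        assert sum(dict(g.degree()).values()) == 2 * len(report.network.edges)


def _net_from_edges(pairs):
    edges = pd.DataFrame(
        [{"lncrna": a, "mrna": b, "rho": 1.0, "p": 2 / 720,
          "overlap_excluded": False, "direction_consistent": True}
         for a, b in pairs]
    )
    return CoexpressionNetwork(edges=edges, excluded=edges.iloc[:0],
                               skipped_pairs=[], n_pairs_tested=len(pairs))


class TestClusters:
    def test_shared_mrna_components_and_acting_alone(self):
        net = _net_from_edges([("A", "m1"), ("A", "m2"), ("B", "m2"),
                               ("B", "m3"), ("C", "m4")])
        clusters = cluster_lncrnas(net)
        members = [c["members"] for c in clusters]
        assert ["A", "B"] in members and ["C"] in members
        assert [c["acting_alone"] for c in clusters] == [False, True]

    def test_identical_neighbour_sets_share_exact_group(self):
        net = _net_from_edges([("A", "m1"), ("A", "m2"), ("B", "m1"), ("B", "m2")])
        clusters = cluster_lncrnas(net)
        assert len(clusters) == 1
        assert len(clusters[0]["exact_groups"]) == 1

    def test_planted_module_count_recovered(self, default_run):
        sim, report = default_run
        # restrict to clusters containing planted lncRNAs
        planted = set(sim.truth.module_lnc_ids())
        clusters = [c for c in report.clusters if set(c["members"]) & planted]
        assert len(clusters) == len(sim.truth.modules)


class TestPathwaySubnetwork:
    def test_disjoint_set_gives_zero_census(self):
        net = _net_from_edges([("A", "m1")])
        census = pathway_subnetwork(net, ["zzz"])
        assert (census["n_lnc"], census["n_mrna"], census["n_edges"]) == (0, 0, 0)

    def test_full_set_reproduces_network_census(self, default_run):
        _, report = default_run
        census = pathway_subnetwork(report.network, set(report.network.edges["mrna"]))
        full = report.network.degree_census()
        assert census["n_edges"] == full["n_edges"]
        assert census["n_lnc"] == full["n_lnc"]

    def test_planted_pathway_census_matches_truth(self, default_run):
        sim, report = default_run
        edges = report.network.edges
        for sid, members in sim.truth.pathways.items():
            census = pathway_subnetwork(report.network, sim.gene_sets.members(sid))
            expect = edges[edges["mrna"].isin(set(members))]
            assert census["n_edges"] == len(expect)
            assert census["n_mrna"] == expect["mrna"].nunique()
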