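"""End-to-end orchestration: filter -> normalize (UQUA + VST) -> DE ->
PCA feature extraction -> candidate intersection -> perfect-correlation
network -> clusters / pathway subnetworks -> guilt-by-association ->
cross-dataset concordance.

``run_all`` takes in-memory objects and returns a :class:`RunReport` whose
``stages`` record every stage's input/output cardinalities (the analysis
funnel) and whose ``thresholds`` echo the configuration verbatim, so a run
is auditable from its report alone. File loading and writing live in
``run_from_files``/``write_outputs`` so the science stays testable without
touching disk.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import concordance as conc
from . import data_model as dm
from . import de as de_mod
from . import enrichment as enr
from . import network as net_mod
from . import normalization as norm
from . import pca as pca_mod

logger = logging.getLogger("lncnet")


@dataclass
class Thresholds:
    """Every cutoff the pipeline applies, in one auditable place."""

    t_log2fc: float = 1.5
    alpha: float = 0.05
    cum_var: float = 0.6
    r_min: float = 0.8
    q_max: float = 0.05
    rho_min: float = 1.0
    p_max: float = 0.005
    enrich_logp: float = 6.0
    enrich_q: float = 0.05
    kappa_min: float = 0.3
    positive_only: bool = False

    def validate(self) -> None:
        for name in ("alpha", "cum_var", "q_max", "p_max", "enrich_q"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"threshold {name}={v} outside (0, 1]")
        if self.t_log2fc < 0 or self.r_min < 0 or self.rho_min < 0:
            raise ValueError("magnitude thresholds must be non-negative")


@dataclass
class RunReport:
    stages: dict = field(default_factory=dict)
    thresholds: dict = field(default_factory=dict)
    # result objects (not serialized by default)
    de_table: pd.DataFrame | None = None
    pca_selection: object | None = None
    candidates: object | None = None
    network: object | None = None
    clusters: list | None = None
    pathway_census: dict | None = None
    enrichment: object | None = None
    assignments: pd.DataFrame | None = None
    term_graph: object | None = None
    separation: dict | None = None
    concordance: object | None = None

    def funnel(self) -> dict:
        return dict(self.stages)


def run_all(
    counts: dm.CountMatrix,
    annotation: dm.GeneAnnotation,
    gene_sets: dm.GeneSetCollection | None = None,
    thresholds: Thresholds | None = None,
    de_table: pd.DataFrame | None = None,
    reference_log2fc: pd.Series | None = None,
    reference_counts: tuple[int, int, int] | None = None,
    disease_set_ids=(),
    lnc_biotypes=dm.DEFAULT_LNC_BIOTYPES,
    pcg_biotypes=dm.DEFAULT_PCG_BIOTYPES,
    seed: int = 0,
) -> RunReport:
    th = thresholds or Thresholds()
    th.validate()
    report = RunReport(thresholds=dataclasses.asdict(th))
    st = report.stages

    # annotated genes only
    annotated = counts.gene_ids.intersection(annotation.gene_ids)
    st["genes_input"] = int(counts.n_genes)
    st["genes_annotated"] = int(len(annotated))
    cm = counts.subset_genes(list(annotated))

    cm = norm.filter_nonzero(cm)
    st["genes_nonzero"] = int(cm.n_genes)

    cm_uqua, _ = norm.uqua_normalize(cm)
    cm_vst, vst_model = norm.vst_transform(cm)
    st["vst_fallback"] = bool(vst_model.used_fallback)

    lnc_ids, pcg_ids, biotype_summary = dm.partition_by_biotype(
        annotation, lnc_biotypes, pcg_biotypes
    )
    lnc_ids = [g for g in lnc_ids if g in cm.gene_ids]
    pcg_ids = [g for g in pcg_ids if g in cm.gene_ids]
    st["n_lncrna"] = len(lnc_ids)
    st["n_pcg"] = len(pcg_ids)
    report.stages["biotype_summary"] = {
        k: round(v, 3) for k, v in biotype_summary["percent"].items()
    }

    if de_table is None:
        de_table = de_mod.internal_de(
            cm_vst, cm_uqua, t_log2fc=th.t_log2fc, alpha=th.alpha
        )
    report.de_table = de_table
    de_genes = de_table[de_table["status"] != "not_de"]
    st["n_de_genes"] = int(len(de_genes))
    de_pcg = [g for g in de_genes.index if g in set(pcg_ids)]
    st["n_de_pcg"] = len(de_pcg)

    # PCA-based feature extraction on the lncRNA VST submatrix
    cm_lnc = cm_vst.subset_genes(lnc_ids)
    sel = pca_mod.run_pca(cm_lnc)
    pca_mod.select_pcs(sel, cum_threshold=th.cum_var)
    selected = pca_mod.extract_features(sel, cm_lnc, r_min=th.r_min, q_max=th.q_max)
    report.pca_selection = sel
    st["k_pcs_selected"] = int(sel.k_selected)
    st["n_pca_selected"] = int(len(selected))
    report.separation = pca_mod.confirm_separation(cm_lnc, list(selected.index))

    cand = de_mod.intersect_candidates(list(selected.index), de_table, lnc_ids)
    report.candidates = cand
    st.update({f"candidates_{k}": v for k, v in cand.summary().items()})

    network = net_mod.build_network(
        cm_uqua,
        cand.candidates,
        de_pcg,
        annotation,
        de_table=de_table,
        rho_min=th.rho_min,
        p_max=th.p_max,
        positive_only=th.positive_only,
        mc_seed=seed,
    )
    report.network = network
    st["network_pairs_tested"] = network.n_pairs_tested
    st.update({f"network_{k}": v for k, v in network.degree_census().items()})
    st["network_overlap_excluded"] = int(len(network.excluded))

    report.clusters = net_mod.cluster_lncrnas(network)
    st["n_lnc_clusters"] = len(report.clusters)
    st["n_lnc_acting_alone"] = sum(c["acting_alone"] for c in report.clusters)

    if gene_sets is not None:
        universe = [g for g in pcg_ids]
        enrichment = enr.hypergeom_enrich(
            de_pcg, gene_sets, universe, th.enrich_logp, th.enrich_q
        )
        report.enrichment = enrichment
        st["n_terms_enriched_q"] = int(enrichment.table["passes_q"].sum()) if len(enrichment.table) else 0
        report.term_graph = enr.kappa_term_graph(
            enrichment, gene_sets, kappa_min=th.kappa_min, by="q"
        )
        report.assignments = enr.assign_lnc_functions(
            network, gene_sets, universe, disease_set_ids,
            th.enrich_logp, th.enrich_q,
        )
        if disease_set_ids:
            report.pathway_census = {
                sid: net_mod.pathway_subnetwork(
                    network, gene_sets.members(sid), de_table
                )
                for sid in disease_set_ids
            }
            st["pathway_census"] = {
                sid: {k: v for k, v in c.items() if k in ("n_lnc", "n_mrna", "n_edges")}
                for sid, c in report.pathway_census.items()
            }

    if reference_log2fc is not None and reference_counts is not None:
        internal = de_table.loc[cand.candidates, "log2fc"]
        down, up, total = reference_counts
        report.concordance = conc.validate_concordance(
            internal, reference_log2fc, down, up, total
        )
        st["concordance_n"] = report.concordance.n_candidates
        st["concordance_k"] = report.concordance.n_concordant
        st["concordance_p"] = report.concordance.p_value

    return report


def write_outputs(report: RunReport, out_dir) -> None:
    """Write the standard output files under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    dm.write_report({"stages": report.stages, "thresholds": report.thresholds},
                    out / "report.json")
    if report.de_table is not None:
        report.de_table.to_csv(out / "de_table.tsv", sep="\t")
    if report.pca_selection is not None:
        report.pca_selection.scree().to_csv(out / "scree.tsv", sep="\t", index=False)
        if report.pca_selection.feature_assoc is not None:
            report.pca_selection.feature_assoc.to_csv(
                out / "features.tsv", sep="\t", index=False
            )
    if report.candidates is not None:
        report.candidates.table.to_csv(out / "candidates.tsv", sep="\t")
    if report.network is not None:
        dm.write_edges(report.network.edges, out / "edges.tsv")
        dm.write_edges(report.network.excluded, out / "excluded_edges.tsv")
        dm.write_graphml(report.network.graph(), out / "network.graphml")
    if report.clusters is not None:
        dm.write_report(report.clusters, out / "clusters.json")
    if report.pathway_census is not None:
        dm.write_report(report.pathway_census, out / "pathway_census.json")
    if report.enrichment is not None:
        report.enrichment.table.drop(columns=["members_in_overlap"]).to_csv(
            out / "enrichment.tsv", sep="\t", index=False
        )
    if report.assignments is not None:
        report.assignments.to_csv(out / "lnc_assignments.tsv", sep="\t")
    if report.concordance is not None:
        res = dataclasses.asdict(report.concordance)
        res["flags"] = {k: (None if pd.isna(v) else bool(v))
                        for k, v in report.concordance.flags.items()}
        dm.write_report(res, out / "concordance.json")


def read_group_map(path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", header=None, names=["sample", "group"])
    return dict(zip(df["sample"], df["group"]))


def run_from_files(
    counts_path,
    groups_path,
    annotation_path,
    annotation_dialect: str = "biomart_tsv",
    gmt_path=None,
    de_table_path=None,
    reference_de_path=None,
    reference_counts: tuple[int, int, int] | None = None,
    disease_set_ids=(),
    thresholds: Thresholds | None = None,
    out_dir=None,
    seed: int = 0,
) -> RunReport:
    """Load inputs from disk, run the pipeline, optionally write outputs."""
    th = thresholds or Thresholds()
    counts = dm.read_counts(counts_path, read_group_map(groups_path))
    ann = dm.read_annotation(annotation_path, annotation_dialect)
    sets = dm.read_gmt(gmt_path) if gmt_path else None
    de_table = (
        de_mod.ingest_de_table(de_table_path, th.t_log2fc, th.alpha)
        if de_table_path
        else None
    )
    ref = None
    if reference_de_path:
        if reference_counts is None:
            raise ValueError("reference DE table requires (down, up, total) counts")
        rdf = pd.read_csv(reference_de_path, sep="\t")
        ref = rdf.set_index(rdf.columns[0]).iloc[:, 0].astype(float)
    report = run_all(
        counts,
        ann,
        sets,
        th,
        de_table=de_table,
        reference_log2fc=ref,
        reference_counts=reference_counts,
        disease_set_ids=disease_set_ids,
        seed=seed,
    )
    if out_dir is not None:
        write_outputs(report, out_dir)
    return report
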