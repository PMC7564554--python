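"""Differential expression: ingest an external DE table or compute a simple
internal one, then intersect DE lncRNAs with the PCA-selected set.

The primary path ingests a DE table computed elsewhere (gene_id, log2FC,
padj) and only applies the status thresholds (|log2FC| >= 1.5 and
BH-adjusted p <= 0.05 by default). The internal route exists so the pipeline
is self-contained on synthetic data: log2 fold changes come from
upper-quartile-normalized group means with a pseudocount of 1 (group means
near zero occur in practice), p-values from a two-sided Welch t-test on the
variance-stabilized values, and adjustment from Benjamini-Hochberg. This is
a deliberately plain stand-in for a negative-binomial Wald test, adequate at
the effect sizes the pipeline targets.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .data_model import CountMatrix, DataModelError, assign_de_status

logger = logging.getLogger("lncnet")


def ingest_de_table(path, t_log2fc: float = 1.5, alpha: float = 0.05) -> pd.DataFrame:
    """Read a TSV with gene_id, log2FC, padj and assign DE status."""
    df = pd.read_csv(path, sep="\t")
    cols = {c.lower(): c for c in df.columns}
    need = {"gene_id", "log2fc", "padj"}
    if not need <= set(cols):
        raise DataModelError(f"DE table must have columns {sorted(need)}")
    df = df.rename(columns={cols["gene_id"]: "gene_id", cols["log2fc"]: "log2fc", cols["padj"]: "padj"})
    for extra in ("mean_healthy", "mean_tumour"):
        if extra not in df.columns:
            df[extra] = np.nan
    return assign_de_status(df, t_log2fc, alpha).set_index("gene_id")


def internal_de(
    cm_vst: CountMatrix,
    cm_uqua: CountMatrix,
    group_healthy: str = "healthy",
    group_tumour: str = "tumour",
    t_log2fc: float = 1.5,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Welch-t DE on VST values with UQUA-mean fold changes.

    log2FC is tumour over healthy. Genes with zero variance in both groups
    and equal means get p = 1.
    """
    for cm in (cm_vst, cm_uqua):
        cm.require_groups(2)
    h_vst = cm_vst.group_columns(group_healthy).to_numpy(float)
    t_vst = cm_vst.group_columns(group_tumour).to_numpy(float)
    h_uq = cm_uqua.group_columns(group_healthy).mean(axis=1)
    t_uq = cm_uqua.group_columns(group_tumour).mean(axis=1)
    if not cm_vst.gene_ids.equals(cm_uqua.gene_ids):
        raise DataModelError("VST and UQUA matrices must share the gene index")

    log2fc = np.log2((t_uq + 1.0) / (h_uq + 1.0))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # degenerate rows handled below
        _, p = stats.ttest_ind(t_vst, h_vst, axis=1, equal_var=False)
    p = np.where(np.isfinite(p), p, 1.0)
    _, padj, _, _ = multipletests(p, method="fdr_bh")
    df = pd.DataFrame(
        {
            "gene_id": cm_vst.gene_ids,
            "log2fc": log2fc.to_numpy(),
            "pvalue": p,
            "padj": padj,
            "mean_healthy": h_uq.to_numpy(),
            "mean_tumour": t_uq.to_numpy(),
        }
    )
    return assign_de_status(df, t_log2fc, alpha).set_index("gene_id")


@dataclass
class CandidateSet:
    """PCA-selected, differentially expressed lncRNAs.

    ``table`` is ordered like a candidate report: down-regulated first,
    ranked by log2FC within direction.
    """

    pca_selected: list[str]
    de_lnc: list[str]
    table: pd.DataFrame
    n_up: int = 0
    n_down: int = 0

    @property
    def candidates(self) -> list[str]:
        return list(self.table.index)

    def summary(self) -> dict:
        return {
            "n_pca_selected": len(self.pca_selected),
            "n_de_lnc": len(self.de_lnc),
            "n_candidates": len(self.table),
            "n_up": self.n_up,
            "n_down": self.n_down,
        }


def intersect_candidates(
    pca_selected, de_table: pd.DataFrame, lnc_ids
) -> CandidateSet:
    """Intersect the PCA-selected lncRNAs with the DE lncRNAs.

    Candidates carry their log2FC, padj and direction, ranked by log2FC
    within direction (most down-regulated first, then most up-regulated
    last), mirroring a signed fold-change table.
    """
    lnc_set = set(lnc_ids)
    de_lnc = [g for g in de_table.index if g in lnc_set and de_table.at[g, "status"] != "not_de"]
    cand = sorted(set(pca_selected) & set(de_lnc))
    if not cand:
        warnings.warn("empty candidate set", stacklevel=2)
    table = de_table.loc[cand, ["log2fc", "padj", "status"]].copy()
    table = table.rename(columns={"status": "direction"})
    table = table.sort_values("log2fc")
    n_down = int((table["direction"] == "down").sum())
    n_up = int((table["direction"] == "up").sum())
    logger.info(
        "intersect_candidates: %d PCA x %d DE lncRNAs -> %d candidates (%d down, %d up)",
        len(set(pca_selected)), len(de_lnc), len(cand), n_down, n_up,
    )
    return CandidateSet(
        pca_selected=sorted(set(pca_selected)),
        de_lnc=sorted(de_lnc),
        table=table,
        n_up=n_up,
        n_down=n_down,
    )
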