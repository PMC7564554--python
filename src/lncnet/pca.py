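"""PCA-based unsupervised feature extraction of discriminative lncRNAs.

The lncRNA submatrix of the variance-stabilized expression values is
decomposed by PCA (genes centered, not rescaled — the VST is the variance
equalizer). Principal components are retained up to a cumulative
explained-variance threshold (0.6 by default), and a lncRNA is selected when
its expression profile across samples correlates with a retained PC's score
vector at |r| >= r_min with a within-PC Benjamini-Hochberg q <= q_max. Both
thresholds apply together; |r| is used because the sign of a component is
arbitrary. A feature qualifying on several retained PCs is assigned to the
one with the largest |r| and counted once, so the per-PC counts form the
"uniquely associated" partition.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import linprog
from statsmodels.stats.multitest import multipletests

from .data_model import CountMatrix, DataModelError

logger = logging.getLogger("lncnet")


@dataclass
class PCASelection:
    """PCA decomposition plus the feature-association bookkeeping."""

    eigenvalues: np.ndarray          # variance per PC, decreasing
    explained_fraction: np.ndarray
    cumulative_fraction: np.ndarray
    scores: pd.DataFrame             # sample x PC
    k_selected: int = 0
    feature_assoc: pd.DataFrame | None = None  # (lncRNA, PC, r, p, q, qualifies)
    selected: pd.DataFrame | None = None       # index lncRNA, column assigned_pc

    def scree(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "pc": [f"PC{i + 1}" for i in range(len(self.eigenvalues))],
                "eigenvalue": self.eigenvalues,
                "fraction": self.explained_fraction,
                "cumulative": self.cumulative_fraction,
            }
        )


def run_pca(cm: CountMatrix) -> PCASelection:
    """PCA of samples in gene space (genes centered across samples).

    With s samples there are at most s-1 non-zero eigenvalues; components
    are ordered by decreasing eigenvalue and scores are mutually orthogonal.
    """
    if cm.n_samples < 3:
        raise DataModelError("PCA needs at least 3 samples")
    x = cm.values.to_numpy(float).T  # samples x genes
    x = x - x.mean(axis=0, keepdims=True)
    if not np.any(x):
        raise DataModelError("constant matrix: PCA undefined")
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    n = x.shape[0]
    eig = s**2 / (n - 1)
    nz = eig > max(eig[0], 1.0) * 1e-12
    eig = eig[nz]
    scores = u[:, nz] * s[nz]
    frac = eig / eig.sum()
    pcs = [f"PC{i + 1}" for i in range(len(eig))]
    return PCASelection(
        eigenvalues=eig,
        explained_fraction=frac,
        cumulative_fraction=np.cumsum(frac),
        scores=pd.DataFrame(scores, index=cm.sample_ids, columns=pcs),
    )


def select_pcs(sel: PCASelection, cum_threshold: float = 0.6, fixed_k: int | None = None) -> int:
    """Smallest k whose cumulative explained variance reaches the threshold."""
    if fixed_k is not None:
        k = min(fixed_k, len(sel.eigenvalues))
    else:
        if not 0 < cum_threshold <= 1:
            raise DataModelError("cum_threshold must be in (0, 1]")
        k = int(np.searchsorted(sel.cumulative_fraction, cum_threshold - 1e-12) + 1)
        k = min(k, len(sel.eigenvalues))
    sel.k_selected = k
    return k


def extract_features(
    sel: PCASelection,
    cm: CountMatrix,
    r_min: float = 0.8,
    q_max: float = 0.05,
    fdr_scope: str = "per_pc",
) -> pd.DataFrame:
    """Select lncRNAs associated with at least one retained PC.

    For each retained PC, Pearson r between every gene's profile and the
    PC scores, two-sided p, and BH-FDR across genes (within each PC by
    default, globally with ``fdr_scope='global'``). Returns the selected
    table (index gene, column ``assigned_pc``, plus r/p/q of the winning
    association); the full association table lands in ``sel.feature_assoc``.
    """
    if sel.k_selected < 1:
        raise DataModelError("call select_pcs first")
    n = cm.n_samples
    if n < 4:
        raise DataModelError("feature-PC correlation needs at least 4 samples")
    x = cm.values.to_numpy(float)  # genes x samples
    xc = x - x.mean(axis=1, keepdims=True)
    xs = xc.std(axis=1)
    rows = []
    for k in range(sel.k_selected):
        pc = sel.scores.iloc[:, k].to_numpy(float)
        pcc = pc - pc.mean()
        denom = xs * pcc.std()
        with np.errstate(invalid="ignore", divide="ignore"):
            r = (xc @ pcc) / (n * denom)
        r = np.clip(np.where(np.isfinite(r), r, 0.0), -1.0, 1.0)
        # two-sided p via the exact beta distribution of r under normality
        ab = (n - 2) / 2.0
        p = 2.0 * stats.beta.sf(np.abs(r), ab, ab, loc=-1.0, scale=2.0)
        p = np.clip(p, 0.0, 1.0)
        rows.append(
            pd.DataFrame(
                {
                    "gene_id": cm.gene_ids,
                    "pc": sel.scores.columns[k],
                    "r": r,
                    "p": p,
                }
            )
        )
    assoc = pd.concat(rows, ignore_index=True)
    if fdr_scope == "per_pc":
        assoc["q"] = assoc.groupby("pc")["p"].transform(
            lambda s: multipletests(s, method="fdr_bh")[1]
        )
    elif fdr_scope == "global":
        assoc["q"] = multipletests(assoc["p"], method="fdr_bh")[1]
    else:
        raise DataModelError(f"unknown fdr_scope {fdr_scope!r}")
    assoc["qualifies"] = (assoc["r"].abs() >= r_min) & (assoc["q"] <= q_max)
    sel.feature_assoc = assoc

    qual = assoc[assoc["qualifies"]].copy()
    qual["abs_r"] = qual["r"].abs()
    best = qual.sort_values("abs_r", ascending=False).drop_duplicates("gene_id")
    selected = best.set_index("gene_id")[["pc", "r", "p", "q"]].rename(
        columns={"pc": "assigned_pc"}
    ).sort_index()
    sel.selected = selected
    counts = selected["assigned_pc"].value_counts().to_dict()
    logger.info("extract_features: %d selected; per-PC unique counts %s", len(selected), counts)
    return selected


def _linearly_separable_2d(points: np.ndarray, labels: np.ndarray) -> bool:
    """Exact 2-d linear separability via an LP feasibility problem."""
    y = np.where(labels == labels[0], 1.0, -1.0)
    # find w, b with y_i (w.x_i + b) >= 1
    a_ub = -(y[:, None] * np.hstack([points, np.ones((len(points), 1))]))
    b_ub = -np.ones(len(points))
    res = linprog(
        c=np.zeros(3),
        A_ub=a_ub,
        b_ub=b_ub,
        bounds=[(None, None)] * 3,
        method="highs",
    )
    return bool(res.success)


def confirm_separation(cm: CountMatrix, selected_ids) -> dict:
    """Re-run PCA on the selected lncRNAs and score group separation.

    Reports the silhouette of the group labels in the (PC1, PC2) plane and
    whether the groups are linearly separable there.
    """
    ids = [g for g in selected_ids if g in cm.gene_ids]
    if not ids:
        warnings.warn("no selected features; skipping separation check", stacklevel=2)
        return {"skipped": True}
    sub = cm.subset_genes(ids)
    sel = run_pca(sub)
    k = min(2, sel.scores.shape[1])
    pts = sel.scores.iloc[:, :k].to_numpy(float)
    if pts.shape[1] == 1:
        pts = np.hstack([pts, np.zeros_like(pts)])
    labels = cm.group.to_numpy()
    from sklearn.metrics import silhouette_score

    sil = float(silhouette_score(pts, labels)) if len(set(labels)) > 1 else float("nan")
    sep = _linearly_separable_2d(pts, labels)
    return {
        "skipped": False,
        "n_features": len(ids),
        "silhouette": sil,
        "linearly_separable": sep,
        "explained_pc1_pc2": float(sel.cumulative_fraction[min(1, len(sel.cumulative_fraction) - 1)]),
    }
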