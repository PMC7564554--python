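# lncnet

Discovery of lncRNA–mRNA co-expression partners from small-cohort bulk
RNA-seq, for transcriptomics researchers who want to assign putative
functions to long non-coding RNAs in a disease contrast (the motivating
setting is childhood B-cell acute lymphoblastic leukaemia, tumour vs
healthy, 3 samples per group).

Most lncRNAs have no annotated function. When a lncRNA's expression tracks
a protein-coding gene's expression perfectly across samples, the
guilt-by-association principle transfers the coding gene's pathway
annotations to the lncRNA. `lncnet` implements that whole chain as a tested
pipeline:

1. **Normalization** — upper-quartile (UQUA) scaling for rank-based steps,
   and a closed-form negative-binomial variance-stabilizing transform (VST)
   under the parametric dispersion trend α(μ) = a/μ + α₀ for PCA.
2. **PCA-based unsupervised feature extraction** — principal components of
   the lncRNA VST matrix are retained up to 60% cumulative variance; a
   lncRNA is kept when its profile correlates with a retained PC at
   |r| ≥ 0.8 with within-PC Benjamini–Hochberg FDR ≤ 0.05.
3. **Differential expression** — an external DE table can be ingested
   (|log₂FC| ≥ 1.5, padj ≤ 0.05), or a self-contained Welch-t-on-VST
   caller is used. Candidates = PCA-selected ∩ DE lncRNAs.
4. **Perfect-correlation network** — every candidate lncRNA × DE
   protein-coding gene pair is tested with Spearman's rho and an **exact
   permutation p-value**. At n = 6 the two-sided tail of |ρ| = 1 is
   2/720 ≈ 0.00278 and the next achievable |ρ| (0.9429) already has
   p = 12/720, so the filter ρ = ±1, p < 0.005 retains exactly the
   perfectly monotone pairs. Pairs with overlapping gene loci are excluded.
5. **Concordance validation** — fold-change signs of the candidates are
   compared with an independent reference dataset; significance is the
   exact one-sided binomial tail P(X ≥ k), X ~ Bin(n, p₀), with p₀ the
   fraction of reference lncRNAs that are DE at all.
6. **Guilt-by-association** — hypergeometric enrichment of each lncRNA's
   co-expressed mRNA set against GMT pathways, a Cohen's-kappa term-
   similarity graph (κ > 0.3), and per-lncRNA pathway membership and
   mRNA-sharing statistics.

A fully specified synthetic-data generator (`lncnet.simulate`) emulates the
study conditions — 3 vs 3 negative-binomial counts, paper-like biotype
proportions, planted DE genes, and planted perfectly rank-concordant
lncRNA–mRNA modules — with complete ground-truth bookkeeping, so every
stage has recovery tests.

## Worked example

```python
from lncnet import SimConfig, simulate, simulate_reference_de, run_all

sim = simulate(SimConfig(seed=0))                      # 2500 genes, 3 vs 3
ref, ref_counts = simulate_reference_de(sim.truth, seed=0)
report = run_all(sim.counts, sim.annotation, sim.gene_sets,
                 reference_log2fc=ref, reference_counts=ref_counts,
                 disease_set_ids=list(sim.truth.pathways), seed=0)
for key in ("genes_nonzero", "n_lncrna", "n_pca_selected",
            "candidates_n_candidates", "network_n_edges",
            "n_lnc_clusters", "concordance_k", "concordance_p"):
    print(key, "=", report.stages[key])
```

prints

```
genes_nonzero = 2418
n_lncrna = 331
n_pca_selected = 11
candidates_n_candidates = 10
network_n_edges = 30
n_lnc_clusters = 5
concordance_k = 9
concordance_p = 0.052740598878681974
```

Reading the funnel: of 2418 expressed genes, 331 are lncRNAs; PCA feature
extraction keeps 11 of them, 10 of which are also differentially expressed
(these are exactly the ten planted module lncRNAs — 8 down-, 2 up-regulated).
All 30 planted lncRNA–mRNA edges are recovered at ρ = 1 with p = 2/720, the
shared-mRNA graph resolves the 5 planted modules, and 9 of the 10
candidates agree in fold-change sign with the simulated reference dataset
(binomial tail p ≈ 0.053 against a 0.61 chance rate). The selected lncRNAs
separate the groups in the PC1/PC2 plane with silhouette 0.93.

The same run is available from the shell:

```sh
lncnet simulate --seed 0 --out-dir sim/
lncnet run-all --counts sim/counts.tsv --groups sim/groups.tsv \
    --annotation sim/annotation.tsv --gmt sim/sets.gmt \
    --reference-de sim/reference_de.tsv --reference-counts 813 407 2000 \
    --disease-sets DIS1,DIS2,DIS3,DIS4 --out-dir run/
```

which writes `report.json`, `edges.tsv`, `network.graphml`, `clusters.json`,
`enrichment.tsv`, `lnc_assignments.tsv` and `concordance.json` under `run/`.

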