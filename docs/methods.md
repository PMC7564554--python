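# Methods

This note documents the statistical models behind `lncnet`, the defaults
and why they are what they are, what the synthetic-data generator does and
does not emulate, and the numerical choices a maintainer would otherwise
have to reverse-engineer.

## Setting and assumptions

The pipeline targets a two-group bulk RNA-seq contrast with very few
biological replicates (the design case is 3 tumour vs 3 healthy samples).
Everything downstream is shaped by that sample size:

* parametric tests have so few degrees of freedom that their tail
  approximations cannot be trusted near the decision thresholds, so the
  co-expression filter uses an *exact* permutation null;
* a perfect Spearman correlation (|ρ| = 1) is an achievable and meaningful
  event at n = 6, which it would not be at n = 50;
* variance estimation per gene is hopeless without pooling, hence the
  parametric dispersion trend.

Counts are modelled as negative binomial with gene dispersion following
α(μ) = a/μ + α₀ (shot noise dominating at low expression, a biological
coefficient-of-variation floor √α₀ at high expression).

## Normalization

**Upper-quartile (UQUA).** Each sample is divided by the 75th percentile of
its *non-zero* counts (linear interpolation between order statistics; the
percentile dialect is fixed because implementations differ), then rescaled
by the across-sample mean of those percentiles so values remain count-like.
Rescaling is cosmetic for every rank-based consumer; `rescale=False` gives
pure division. UQUA is invariant to global per-sample scaling and
order-preserving within a sample — both are property-tested. Samples with
fewer than four non-zero genes have no meaningful upper quartile and are
rejected.

**Variance-stabilizing transform (VST).** Size factors come from the
median-of-ratios estimator over genes expressed in all samples. Gene-wise
dispersions are method-of-moments on the common scale,
α̂ = (s² − ξ̄μ̂)/μ̂² with ξ̄ the mean reciprocal size factor. The trend
α(μ) = a/μ + α₀ is fitted by least squares on *relative* residuals
(α̂/α(μ) − 1) with iterative exclusion of genes whose ratio to the trend
leaves [10⁻⁴, 15]. This matters: at n = 6 the raw dispersion estimates are
extremely noisy and right-skewed, and an unweighted fit inflates α₀ by an
order of magnitude, which quietly destroys the stabilization at high
expression. The transform itself is the closed form

    vst(q) = log₂( (1 + a + 2α₀q + 2√(α₀q(1 + a + α₀q))) / (4α₀) ),

strictly increasing in q for α₀ > 0 and asymptotically log₂-like. If the
fit degenerates (α₀ ≤ 0 or fewer than 10 usable genes) the code falls back
to log₂(q + 1) and flags the model, because a silently broken VST would
bias the PCA. The acceptance surface of this component is the
variance-flattening *property* (strata SDs within 2×), not bit-equality
with any external implementation.

## Differential expression

The primary path ingests an externally computed table (gene, log₂FC, padj)
and only applies status thresholds (|log₂FC| ≥ 1.5, padj ≤ 0.05,
Benjamini–Hochberg). The internal caller — needed so synthetic runs are
self-contained — uses log₂((mean_tumour+1)/(mean_healthy+1)) on UQUA values
(the pseudocount guards the near-zero means that strongly suppressed genes
actually reach) and a two-sided Welch t-test on VST values with BH
adjustment. Welch-t on variance-stabilized data is a deliberately plain
stand-in for a count-model Wald test; at n = 3 + 3 its effective degrees of
freedom sit between 2 and 4, so only effects with t ≳ 10 survive BH. That
power profile is real and is reflected in the generator calibration below.

## PCA-based feature extraction

Genes are centered but not rescaled before PCA — the VST is the variance
equalizer, and rescaling would re-amplify the noise floor of flat genes.
With s samples there are at most s − 1 non-zero components. Components are
retained up to 60% cumulative explained variance (configurable, or a fixed
k). A lncRNA is selected when its profile correlates with a retained PC at
|r| ≥ 0.8 **and** within-PC BH FDR ≤ 0.05; the conjunction is the only
reading consistent with using both a correlation floor and an FDR
criterion, and each is independently configurable. |r| rather than signed r
is used because component signs are arbitrary; selection is property-tested
to be invariant under sign flips and monotone in both thresholds. Features
qualifying on several PCs are assigned to the PC with the largest |r| and
counted once, producing the "uniquely associated" per-PC partition.
Pearson p-values use the exact beta distribution of r under normality;
at n = 6 this calibrates against the full permutation distribution to
within a few hundredths, which the suite checks.

The selected set is validated by re-running PCA on it alone and scoring the
group silhouette in the (PC1, PC2) plane plus exact 2-d linear separability
via a linear-programming feasibility problem (deterministic, no solver
randomness).

## Exact small-sample Spearman test

For untied vectors the null distribution of ρ over all n! rank orders is
enumerated once per n (n ≤ 9) and cached; the two-sided p-value is the tail
mass of |ρ|. The tolerance for "perfect" is |ρ − 1| ≤ 10⁻¹²; tied ranks can
never reach it (average ranks strictly shrink |ρ|), so ties disqualify
perfection by construction, and tied inputs get a seeded Monte-Carlo
permutation p (10⁵ draws). Above n = 9 the t approximation is adequate and
is used. The load-bearing facts at n = 6: P(|ρ| = 1) = 2/720 ≈ 0.00278 and
P(|ρ| ≥ 0.9429) = 12/720 ≈ 0.0167, so the network filter ρ = ±1,
p < 0.005 admits exactly the perfectly monotone pairs — an asymptotic
p-value here would be simply wrong.

## Network, clusters, pathway census

All candidate-lncRNA × DE-PCG pairs are tested on the UQUA scale. Retained
pairs whose loci overlap on the same chromosome (strand-agnostic, any
shared base) are excluded and logged: perfect correlation between
overlapping genes is better explained by shared-locus artefacts. Both
correlation signs are retained by default (`positive_only` exists).
lncRNA clusters are connected components of the share-an-mRNA graph;
identical-neighbour-set groups and acting-alone singletons are reported
separately, since "share some" and "share all" answer different questions.
Pathway subnetworks are the edge subsets whose mRNA belongs to a gene set,
with node DE directions attached for rendering.

## Concordance validation

A candidate is concordant when its internal and reference log₂FC agree in
sign; zero fold changes are indeterminate and excluded from n rather than
counted discordant. The chance success probability p₀ is the fraction of
reference-dataset lncRNAs that are DE at all (down + up over total), used
at full precision by default with a `rounded_p0` override for matching
published figures. Significance is the exact one-sided upper tail
P(X ≥ k), X ~ Bin(n, p₀), summed term by term. One-sided "greater" is the
scientifically relevant alternative — the question is whether concordance
exceeds what reference-DE membership alone would produce — and it is the
sidedness that reproduces the worked value 0.007645 for k = 25, n = 30,
p₀ = 0.61.

## Guilt-by-association

Enrichment is the upper-tail (cumulative) hypergeometric test of a query
list against GMT sets, BH-corrected across sets, with two filters reported
side by side: −log₁₀(p) > 6 and q ≤ 0.05. The universe defaults to all
annotated protein-coding genes in the matrix; query genes outside the
universe are dropped and logged rather than silently kept. Term similarity
is Cohen's κ between binary membership vectors over the union of
significant-term genes; κ > 0.3 draws an edge and components are term
clusters. Per-lncRNA assignment enriches its co-expressed mRNA set, records
disease-set memberships, and tabulates unique vs shared mRNAs with overlap
partners — the statistics a Circos overlap plot would draw.

## Synthetic data: what it emulates, what it does not

The generator produces a 3 vs 3 cohort of NB counts (2500 genes) with
paper-like biotype proportions (73% protein-coding, 13.6% lncRNA split
across six sub-biotypes, 3.1% short non-coding, 9.8% pseudogene, 0.37%
minor classes), 3% all-zero rows, non-overlapping genomic intervals with
controllable overlap injections, and GMT sets seeded with module mRNAs.

Two modelling choices deserve emphasis:

**A shared severity axis.** Within-group variation of non-module DE genes
is driven by one latent per-sample factor (multipliers 0.8/1.0/1.25,
applied with the sign of the gene's effect) — patients differ in blast
fraction and stage, so DE genes co-vary within groups. This is not
cosmetic: if DE genes fluctuated independently, any two group-separated DE
genes would match sample orderings at ~1/36 per pair, and chance "perfect"
edges would swamp the exact-test null rate of 2/720. With a shared axis,
non-module orderings concentrate on the severity ordering.

**Module orderings far from the severity mode.** Each planted module
(2 lncRNAs + 3 mRNAs sharing one strict per-sample ordering on the UQUA
scale) gets within-group orderings at Kendall distance ≥ 2 per group from
the ordering the severity axis imposes on same-direction DE genes,
pairwise distinct across modules and never the reversal of another
module's ordering. Chance coincidence between a module lncRNA and a
non-module DE gene then requires count noise to cross at least two
specific adjacent severity gaps in each group simultaneously, which is
vanishingly rare; across 14 calibration seeds no false perfect pair
occurred against an allowance of ~6.

Module counts are rejection-sampled per gene until the realized UQUA-scale
ordering matches the module target strictly (no ties, bounded retries,
final verification against recomputed UQUA factors). Calibration of the
remaining defaults follows from the Welch-t power analysis: module genes
live at high expression (means 5×10³–2×10⁴, where count noise is ≈0.15
log₂ units), module |log₂FC| is drawn from [3.0, 5.3] (the strong,
reliably detectable tier — two-thirds of the motivating study's candidates
exceed 3), module multipliers are 0.9/1.0/1.11 (gaps of one noise SD
suffice for the rejection sampler, while keeping within-group SD small
enough for t ≳ 15), and non-module DE genes use means in [800, 8000] with
|log₂FC| in [1.5, 5.3], giving recall ≈ 0.85–0.95 at |log₂FC| ≥ 2.5 and
realistic misses below it. The dispersion trend defaults a = 6, α₀ = 0.01
with base means log-uniform on [1, 2×10⁴] make the mean–variance
relationship strong enough that variance flattening is visible (raw-log₂
strata SDs spread >5×, VST ≈ 1.1×).

What the generator does **not** emulate: batch effects, library-size
outliers, GC/length biases, correlated null genes, isoform structure, or
any read-level process. Passing recovery tests therefore demonstrates that
the pipeline's logic is correct under its own model assumptions, not that
the assumptions hold for any particular real dataset — with n = 3 + 3 the
method remains a hypothesis-generating screen.

The simulated reference dataset for concordance flips a configurable
fraction of fold-change signs (default 1/6, matching the ~25/30 concordance
regime the method is meant to detect) and reports a reference lncRNA
population of 2000 with a 0.61 DE rate (down:up ≈ 2:1), fixing p₀.

## Numerical choices and degenerate inputs

* Perfection tolerance |ρ − 1| ≤ 10⁻¹²; constant vectors raise and the
  pair is skipped with a log entry.
* BH is used for every multiple-testing correction.
* PCA eigenvalues below 10⁻¹² of the leading one are treated as zero.
* `select_pcs` ties break toward the smaller k (first k reaching the
  threshold); feature-to-PC assignment ties break toward the larger |r|.
* Genes absent from the annotation are dropped with a logged count;
  all-zero genes are removed before normalization.
* Welch p-values that come back non-finite (zero variance in both groups,
  equal means) are set to 1.
* Every stochastic step (Monte-Carlo ties, the generator) takes an explicit
  seed; the pipeline is byte-deterministic given (inputs, config, seed).

## Known limitations

* The internal DE caller is a stand-in; with three replicates it misses
  moderate effects (|log₂FC| < 2.5) at low expression, and the candidate
  funnel inherits that attrition. Ingesting a dedicated count-model DE
  table is the recommended path on real data.
* The perfect-correlation filter is intentionally brittle at larger n:
  for n ≫ 6, |ρ| = 1 becomes vanishingly rare under noise and the
  threshold should be relaxed via `rho_min`/`p_max`.
* Enrichment treats gene sets as flat lists: no ontology DAG traversal or
  redundancy collapsing beyond the kappa clustering.
* The genomic-overlap veto is strand-agnostic and interval-based only.
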