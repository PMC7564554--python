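"""Synthetic two-group RNA-seq data with planted structure for every
pipeline stage, plus ground-truth bookkeeping for recovery tests.

The generator emulates a small case/control bulk RNA-seq contrast
(3 vs 3 by default):

* negative-binomial counts with a dispersion-mean trend
  ``alpha(mu) = a/mu + alpha0``;
* a biotype-annotated gene universe with paper-like proportions
  (73% protein-coding, ~13.6% long non-coding split across sub-biotypes,
  plus short non-coding, pseudogene and minor classes);
* planted differentially expressed genes at |log2FC| in a configurable
  range, whose within-group variation is driven by a shared latent
  "severity" axis — patients in a real cohort differ in blast fraction
  and disease stage, so DE genes co-vary within groups rather than
  fluctuating independently;
* planted lncRNA-mRNA modules whose members share one strict per-sample
  ordering on the upper-quartile scale (counts are re-drawn until no
  within-module rank ties or inversions remain), so each module survives a
  perfect-Spearman filter by construction. Module lncRNAs are also DE and
  group-discriminative. Module orderings are chosen pairwise distinct,
  never the reversal of one another, and at least two adjacent
  transpositions away (per group) from the ordering the severity axis
  imposes on same-direction DE genes: chance ordering coincidences between
  module lncRNAs and non-module DE genes are then vanishingly rare, and
  false perfect pairs occur at close to the exact-test null rate;
* non-overlapping genomic intervals with controllable overlap injections;
* GMT gene sets: "disease" sets seeded with module mRNAs (plus unrelated
  fillers) and random background sets.

Everything derives from one ``numpy`` Generator seeded by ``SimConfig.seed``;
the same seed reproduces byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_model import CountMatrix, GeneAnnotation, GeneSetCollection
from .normalization import uqua_normalize

logger = logging.getLogger("lncnet")

#: Biotype proportions of annotated genes (renormalized to sum to 1).
DEFAULT_BIOTYPE_PROPORTIONS = {
    "protein_coding": 0.73,
    "antisense": 0.059,
    "lincRNA": 0.047,
    "sense_intronic": 0.017,
    "processed_transcript": 0.009,
    "sense_overlapping": 0.0036,
    "3prime_overlapping_ncRNA": 0.0002,
    "miRNA": 0.031,
    "pseudogene": 0.098,
    "IG_V_gene": 0.0037,
}

LNC_CLASSES = (
    "antisense",
    "lincRNA",
    "processed_transcript",
    "sense_intronic",
    "sense_overlapping",
    "3prime_overlapping_ncRNA",
)


@dataclass
class SimConfig:
    """Study conditions for the synthetic cohort."""

    n_genes: int = 2500
    samples_per_group: int = 3
    biotype_proportions: dict = field(
        default_factory=lambda: dict(DEFAULT_BIOTYPE_PROPORTIONS)
    )
    zero_fraction: float = 0.03
    # base expression (log-uniform) by role
    mean_range: tuple[float, float] = (1.0, 20000.0)
    de_mean_range: tuple[float, float] = (800.0, 8000.0)
    module_mean_range: tuple[float, float] = (5000.0, 20000.0)
    # NB dispersion trend alpha(mu) = a/mu + alpha0
    dispersion_a: float = 6.0
    dispersion_a0: float = 0.01
    # differential expression
    de_fraction: float = 0.05
    de_log2fc_range: tuple[float, float] = (1.5, 5.3)
    de_down_fraction: float = 0.5
    # perfect modules
    n_modules: int = 5
    lnc_per_module: int = 2
    mrnas_per_module: int = 3
    module_log2fc_range: tuple[float, float] = (3.0, 5.3)
    module_down_fraction: float = 0.8
    # within-group multiplicative spread (ascending)
    severity_multipliers: tuple[float, ...] = (0.8, 1.0, 1.25)
    module_multipliers: tuple[float, ...] = (0.9, 1.0, 1.11)
    # genome layout
    n_chromosomes: int = 6
    n_overlap_pairs: int = 0
    # pathways
    n_disease_sets: int = 4
    n_background_sets: int = 12
    background_set_size: int = 25
    disease_filler_genes: int = 10
    max_retries: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.biotype_proportions.values())
        if abs(total - 1.0) > 1e-9:
            self.biotype_proportions = {
                k: v / total for k, v in self.biotype_proportions.items()
            }
        if len(self.severity_multipliers) != self.samples_per_group:
            raise ValueError("need one severity multiplier per within-group sample")
        if self.n_modules > 0 and self.samples_per_group != 3:
            raise ValueError(
                "planted perfect modules are designed for the 3 vs 3 contrast"
            )


@dataclass
class TruthTable:
    """Planted ground truth emitted alongside the synthetic data."""

    de: pd.DataFrame               # gene_id, log2fc, direction, role
    modules: list[dict]            # module_id, direction, lnc_ids, mrna_ids, sample_order
    zero_genes: list[str]
    injected_overlaps: list[tuple[str, str]]
    pathways: dict[str, list[str]]  # disease set id -> module mRNA members
    severity_order: list[str]       # samples by increasing severity, per group concat

    def module_lnc_ids(self) -> list[str]:
        return [ln for m in self.modules for ln in m["lnc_ids"]]

    def module_edges(self) -> list[tuple[str, str]]:
        return [
            (ln, mr)
            for m in self.modules
            for ln in m["lnc_ids"]
            for mr in m["mrna_ids"]
        ]


@dataclass
class SimResult:
    counts: CountMatrix
    annotation: GeneAnnotation
    gene_sets: GeneSetCollection
    truth: TruthTable


# ---------------------------------------------------------------------------
# ordering machinery
# ---------------------------------------------------------------------------

_PERMS3 = [np.array(p) for p in itertools.permutations(range(3))]


def _kendall(r1: np.ndarray, r2: np.ndarray) -> int:
    n = len(r1)
    d = 0
    for i in range(n):
        for j in range(i + 1, n):
            if np.sign(r1[i] - r1[j]) != np.sign(r2[i] - r2[j]):
                d += 1
    return d


def _module_rank_choices(severity_ranks: np.ndarray, direction: str) -> list[np.ndarray]:
    """Within-group rank vectors far from the severity-induced ordering.

    Same-direction non-module DE genes order within a group like the
    severity axis (up genes) or its reversal (down genes); module orderings
    at Kendall distance >= 2 from that mode are essentially unreachable by
    count noise around it.
    """
    mode = severity_ranks if direction == "up" else (2 - severity_ranks)
    return [p for p in _PERMS3 if _kendall(p, mode) >= 2]


def _allocate_counts(n: int, proportions: dict) -> dict:
    raw = {k: v * n for k, v in proportions.items()}
    counts = {k: int(np.floor(v)) for k, v in raw.items()}
    short = n - sum(counts.values())
    for k in sorted(raw, key=lambda k: raw[k] - np.floor(raw[k]), reverse=True)[:short]:
        counts[k] += 1
    return counts


# ---------------------------------------------------------------------------
# simulate
# ---------------------------------------------------------------------------

def _nb_draw(rng, mean: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    lam = rng.gamma(shape=1.0 / alpha, scale=mean * alpha)
    return rng.poisson(lam)


def simulate(cfg: SimConfig) -> SimResult:
    """Generate counts, annotation, gene sets and the truth table."""
    rng = np.random.default_rng(cfg.seed)
    npg = cfg.samples_per_group
    samples = [f"H{i + 1}" for i in range(npg)] + [f"T{i + 1}" for i in range(npg)]
    group = pd.Series(
        ["healthy"] * npg + ["tumour"] * npg, index=samples
    )
    is_tumour = np.array([0] * npg + [1] * npg, dtype=float)

    # --- gene universe -----------------------------------------------------
    class_counts = _allocate_counts(cfg.n_genes, cfg.biotype_proportions)
    biotypes = np.array(
        [bt for bt, c in class_counts.items() for _ in range(c)], dtype=object
    )
    rng.shuffle(biotypes)
    gene_ids = np.array([f"G{i:05d}" for i in range(cfg.n_genes)], dtype=object)
    lnc_mask = np.isin(biotypes, LNC_CLASSES)
    pcg_mask = biotypes == "protein_coding"

    # --- roles -------------------------------------------------------------
    role = np.full(cfg.n_genes, "null", dtype=object)
    idx_all = np.arange(cfg.n_genes)

    n_zero = int(round(cfg.zero_fraction * cfg.n_genes))
    zero_idx = rng.choice(idx_all, size=n_zero, replace=False)
    role[zero_idx] = "zero"

    free = lambda mask: idx_all[(role == "null") & mask]

    n_mod_down = int(round(cfg.module_down_fraction * cfg.n_modules))
    module_specs = []
    for m in range(cfg.n_modules):
        direction = "down" if m < n_mod_down else "up"
        lnc_ids_m = rng.choice(free(lnc_mask), size=cfg.lnc_per_module, replace=False)
        role[lnc_ids_m] = "module_lnc"
        mrna_ids_m = rng.choice(free(pcg_mask), size=cfg.mrnas_per_module, replace=False)
        role[mrna_ids_m] = "module_mrna"
        module_specs.append(
            {"module_id": f"M{m + 1}", "direction": direction,
             "lnc_idx": lnc_ids_m, "mrna_idx": mrna_ids_m}
        )

    n_de = int(round(cfg.de_fraction * cfg.n_genes))
    n_module_genes = cfg.n_modules * (cfg.lnc_per_module + cfg.mrnas_per_module)
    n_extra_de = max(0, n_de - n_module_genes)
    # non-module DE genes are drawn outside the lncRNA classes: planted
    # lncRNA dysregulation is carried entirely by the modules
    extra_pool = idx_all[(role == "null") & ~lnc_mask]
    extra_de_idx = rng.choice(extra_pool, size=min(n_extra_de, len(extra_pool)), replace=False)
    role[extra_de_idx] = "de"

    # --- expression model --------------------------------------------------
    lo, hi = cfg.mean_range
    base_mean = np.exp(rng.uniform(np.log(lo), np.log(hi), cfg.n_genes))
    d_lo, d_hi = cfg.de_mean_range
    base_mean[role == "de"] = np.exp(
        rng.uniform(np.log(d_lo), np.log(d_hi), (role == "de").sum())
    )
    m_lo, m_hi = cfg.module_mean_range
    mod_mask = np.isin(role, ["module_lnc", "module_mrna"])
    base_mean[mod_mask] = np.exp(
        rng.uniform(np.log(m_lo), np.log(m_hi), mod_mask.sum())
    )

    lfc = np.zeros(cfg.n_genes)
    de_sel = role == "de"
    f_lo, f_hi = cfg.de_log2fc_range
    mag = rng.uniform(f_lo, f_hi, de_sel.sum())
    sign = np.where(rng.random(de_sel.sum()) < cfg.de_down_fraction, -1.0, 1.0)
    lfc[de_sel] = sign * mag
    mf_lo, mf_hi = cfg.module_log2fc_range
    for spec in module_specs:
        s = -1.0 if spec["direction"] == "down" else 1.0
        for gi in np.concatenate([spec["lnc_idx"], spec["mrna_idx"]]):
            lfc[gi] = s * rng.uniform(mf_lo, mf_hi)

    # severity axis: per-group assignment of the within-group multipliers
    sev_rank = {}
    for g, cols in (("healthy", range(npg)), ("tumour", range(npg, 2 * npg))):
        sev_rank[g] = rng.permutation(npg)
    w = np.empty(2 * npg)
    mult = np.array(sorted(cfg.severity_multipliers))
    w[:npg] = mult[sev_rank["healthy"]]
    w[npg:] = mult[sev_rank["tumour"]]

    # per-module within-group orderings, far from the severity mode,
    # pairwise distinct, never a reversal of another module's ordering
    mod_mult = np.array(sorted(cfg.module_multipliers))
    used_combos: set[tuple] = set()
    forbidden: set[tuple] = set()
    for spec in module_specs:
        choices_h = _module_rank_choices(sev_rank["healthy"], spec["direction"])
        choices_t = _module_rank_choices(sev_rank["tumour"], spec["direction"])
        combos = [
            (tuple(a), tuple(b)) for a in choices_h for b in choices_t
        ]
        rng.shuffle(combos)
        for combo in combos:
            if combo not in used_combos and combo not in forbidden:
                break
        else:
            raise RuntimeError("exhausted module ordering combinations")
        used_combos.add(combo)
        rev = (tuple(2 - np.array(combo[0])), tuple(2 - np.array(combo[1])))
        forbidden.add(rev)
        rh, rt = np.array(combo[0]), np.array(combo[1])
        spec["rank_h"], spec["rank_t"] = rh, rt
        spec["multiplier"] = np.concatenate([mod_mult[rh], mod_mult[rt]])

    # per-gene per-sample means
    mean_matrix = np.empty((cfg.n_genes, 2 * npg))
    for i in range(cfg.n_genes):
        if role[i] in ("null", "zero"):
            mean_matrix[i] = base_mean[i]
        elif role[i] == "de":
            sev = w ** np.sign(lfc[i])
            mean_matrix[i] = base_mean[i] * 2.0 ** (lfc[i] * is_tumour) * sev
        else:
            mean_matrix[i] = base_mean[i] * 2.0 ** (lfc[i] * is_tumour)
    for spec in module_specs:
        for gi in np.concatenate([spec["lnc_idx"], spec["mrna_idx"]]):
            mean_matrix[gi] = base_mean[gi] * 2.0 ** (lfc[gi] * is_tumour) * spec["multiplier"]

    alpha = cfg.dispersion_a / base_mean + cfg.dispersion_a0
    counts = _nb_draw(rng, mean_matrix, alpha[:, None]).astype(np.int64)
    counts[zero_idx] = 0
    # genes that happened to draw all zeros but are structural get one count
    structural = np.isin(role, ["de", "module_lnc", "module_mrna"])
    dead = structural & (counts.sum(axis=1) == 0)
    if dead.any():  # essentially impossible at the default means
        counts[dead, 0] = 1

    values = pd.DataFrame(counts, index=gene_ids, columns=samples)
    cm = CountMatrix(values, group, "raw")

    # --- enforce shared strict orderings on the UQUA scale -----------------
    for _attempt in range(3):
        _, uq_model = uqua_normalize(cm)
        div = uq_model.scale_factors.to_numpy(float)
        for spec in module_specs:
            # target ordering: direction block structure plus the module's
            # within-group multipliers, measured on the UQUA scale
            s = -1.0 if spec["direction"] == "down" else 1.0
            target_score = 2.0 ** (s * 3.0 * is_tumour) * spec["multiplier"] / div
            target_order = np.argsort(target_score, kind="stable")
            spec["sample_order"] = [samples[j] for j in target_order]
            for gi in np.concatenate([spec["lnc_idx"], spec["mrna_idx"]]):
                gene = gene_ids[gi]
                for _retry in range(cfg.max_retries):
                    vals = cm.values.loc[gene].to_numpy(float) / div
                    if np.all(np.diff(vals[target_order]) > 0):
                        break
                    new = _nb_draw(rng, mean_matrix[gi], np.full(2 * npg, alpha[gi]))
                    cm.values.loc[gene] = new
                else:
                    raise RuntimeError(
                        f"could not realize a strict ordering for {gene}; "
                        "increase the mean separation (module_multipliers or "
                        "module_log2fc_range)"
                    )
        # verify with the factors the final matrix actually induces
        cm_uq, _ = uqua_normalize(cm)
        ok = True
        for spec in module_specs:
            order = spec["sample_order"]
            for gi in np.concatenate([spec["lnc_idx"], spec["mrna_idx"]]):
                vals = cm_uq.values.loc[gene_ids[gi], order].to_numpy(float)
                if not np.all(np.diff(vals) > 0):
                    ok = False
        if ok:
            break
    else:
        raise RuntimeError("module orderings unstable under UQUA refitting")

    # --- annotation --------------------------------------------------------
    ann = _layout_genome(rng, cfg, gene_ids, biotypes)
    injected = _inject_overlaps(rng, cfg, ann, gene_ids, role, lnc_mask, pcg_mask)

    # --- pathways ----------------------------------------------------------
    sets, pathways = _build_gene_sets(rng, cfg, gene_ids, role, pcg_mask, module_specs)

    # --- truth -------------------------------------------------------------
    de_records = []
    for i in idx_all[np.isin(role, ["de", "module_lnc", "module_mrna"])]:
        de_records.append(
            {
                "gene_id": gene_ids[i],
                "log2fc": lfc[i],
                "direction": "down" if lfc[i] < 0 else "up",
                "role": role[i],
                "biotype": biotypes[i],
            }
        )
    modules_out = [
        {
            "module_id": spec["module_id"],
            "direction": spec["direction"],
            "lnc_ids": [gene_ids[i] for i in spec["lnc_idx"]],
            "mrna_ids": [gene_ids[i] for i in spec["mrna_idx"]],
            "sample_order": spec["sample_order"],
        }
        for spec in module_specs
    ]
    sev_order = (
        [samples[i] for i in np.argsort(w[:npg], kind="stable")]
        + [samples[npg + i] for i in np.argsort(w[npg:], kind="stable")]
    )
    truth = TruthTable(
        de=pd.DataFrame(de_records).set_index("gene_id") if de_records else pd.DataFrame(),
        modules=modules_out,
        zero_genes=[gene_ids[i] for i in sorted(zero_idx)],
        injected_overlaps=injected,
        pathways=pathways,
        severity_order=sev_order,
    )
    return SimResult(counts=cm, annotation=ann, gene_sets=sets, truth=truth)


def _layout_genome(rng, cfg, gene_ids, biotypes) -> GeneAnnotation:
    order = rng.permutation(len(gene_ids))
    cursors = {f"chr{c + 1}": 1 for c in range(cfg.n_chromosomes)}
    recs = {}
    prefix = {bt: 0 for bt in set(biotypes)}
    for k, i in enumerate(order):
        chrom = f"chr{(k % cfg.n_chromosomes) + 1}"
        start = cursors[chrom] + int(rng.integers(1000, 5000))
        length = int(rng.integers(2000, 20000))
        end = start + length - 1
        cursors[chrom] = end + 1
        prefix[biotypes[i]] += 1
        recs[i] = {
            "gene_id": gene_ids[i],
            "symbol": f"{biotypes[i][:3].upper()}{prefix[biotypes[i]]:04d}",
            "biotype": biotypes[i],
            "chrom": chrom,
            "start": start,
            "end": end,
            "strand": "+" if rng.random() < 0.5 else "-",
        }
    table = pd.DataFrame([recs[i] for i in range(len(gene_ids))])
    return GeneAnnotation(table)


def _inject_overlaps(rng, cfg, ann, gene_ids, role, lnc_mask, pcg_mask):
    """Relocate a few protein-coding genes onto lncRNA loci (truth-logged)."""
    injected = []
    if cfg.n_overlap_pairs <= 0:
        return injected
    idx_all = np.arange(len(gene_ids))
    lnc_pool = idx_all[lnc_mask & (role == "null")]
    pcg_pool = idx_all[pcg_mask & (role == "null")]
    n = min(cfg.n_overlap_pairs, len(lnc_pool), len(pcg_pool))
    lncs = rng.choice(lnc_pool, size=n, replace=False)
    pcgs = rng.choice(pcg_pool, size=n, replace=False)
    t = ann.table.set_index("gene_id")
    for li, pi in zip(lncs, pcgs):
        lg, pg = gene_ids[li], gene_ids[pi]
        mid = (t.at[lg, "start"] + t.at[lg, "end"]) // 2
        span = t.at[pg, "end"] - t.at[pg, "start"]
        t.at[pg, "chrom"] = t.at[lg, "chrom"]
        t.at[pg, "start"] = int(mid)
        t.at[pg, "end"] = int(mid + span)
        injected.append((lg, pg))
    ann.table = t.reset_index()
    return injected


def _build_gene_sets(rng, cfg, gene_ids, role, pcg_mask, module_specs):
    idx_all = np.arange(len(gene_ids))
    filler_pool = list(gene_ids[pcg_mask & (role == "null")])
    sets = {}
    pathways = {}
    for k in range(cfg.n_disease_sets):
        sid = f"DIS{k + 1}"
        members = []
        for m, spec in enumerate(module_specs):
            if m % cfg.n_disease_sets == k:
                members.extend(gene_ids[i] for i in spec["mrna_idx"])
        pathways[sid] = list(members)
        fillers = rng.choice(filler_pool, size=cfg.disease_filler_genes, replace=False)
        members = list(members) + list(fillers)
        if not members:
            members = list(fillers)
        sets[sid] = (f"disease pathway {k + 1}", members)
    all_pcg = list(gene_ids[pcg_mask])
    for k in range(cfg.n_background_sets):
        sid = f"BG{k + 1}"
        members = rng.choice(all_pcg, size=cfg.background_set_size, replace=False)
        sets[sid] = (f"background set {k + 1}", list(members))
    return GeneSetCollection(sets), pathways


# ---------------------------------------------------------------------------
# reference dataset for concordance validation
# ---------------------------------------------------------------------------

def simulate_reference_de(
    truth: TruthTable,
    flip_fraction: float = 1.0 / 6.0,
    ref_de_rate: float = 0.61,
    n_reference_lnc: int = 2000,
    seed: int = 0,
) -> tuple[pd.Series, tuple[int, int, int]]:
    """Reference-dataset log2 fold changes plus (down, up, total) lnc counts.

    Planted DE genes keep their fold-change sign except a ``flip_fraction``
    of them; the reference lncRNA population has ``ref_de_rate`` of its
    ``n_reference_lnc`` genes differentially expressed (down twice as often
    as up, as is typical of a malignant-vs-normal contrast), which fixes the
    chance-success probability of the binomial concordance test.
    """
    if not 0.0 <= flip_fraction <= 1.0:
        raise ValueError("flip_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    out = {}
    for gene_id, row in truth.de.iterrows():
        s = np.sign(row["log2fc"])
        if rng.random() < flip_fraction:
            s = -s
        out[gene_id] = s * rng.uniform(0.5, 5.0)
    ref = pd.Series(out, dtype=float)
    n_de = int(round(ref_de_rate * n_reference_lnc))
    n_down = int(round(n_de * 2 / 3))
    n_up = n_de - n_down
    return ref, (n_down, n_up, n_reference_lnc)
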