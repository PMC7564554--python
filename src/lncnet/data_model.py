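"""Core domain types and on-disk formats.

Everything downstream operates on three tables:

* :class:`CountMatrix` — a gene x sample expression matrix with per-sample
  group labels (``healthy`` vs ``tumour`` by convention, but any two or more
  labels work) and a record of which normalization has been applied.
* :class:`GeneAnnotation` — per-gene biotype and genomic interval, used to
  split genes into lncRNA / protein-coding classes and to veto co-expression
  edges between genes whose loci overlap.
* :class:`GeneSetCollection` — named gene sets (GMT format) used as the
  pathway vocabulary for enrichment.

Genomic coordinates are 1-based inclusive (GTF convention) everywhere.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("lncnet")

#: Ensembl biotypes treated as long non-coding by default.  Configurable
#: because Ensembl renamed several classes across releases.
DEFAULT_LNC_BIOTYPES = (
    "antisense",
    "lincRNA",
    "processed_transcript",
    "sense_intronic",
    "sense_overlapping",
    "3prime_overlapping_ncRNA",
)

DEFAULT_PCG_BIOTYPES = ("protein_coding",)


class DataModelError(ValueError):
    """Raised when an input file or container violates an invariant."""


# ---------------------------------------------------------------------------
# CountMatrix
# ---------------------------------------------------------------------------

@dataclass
class CountMatrix:
    """Gene x sample expression values plus sample group labels.

    Parameters
    ----------
    values:
        DataFrame indexed by gene id with one column per sample. Raw counts
        must be non-negative integers; normalized values are reals.
    group:
        Series mapping sample id -> group label, aligned with the columns.
    normalization_state:
        One of ``raw``, ``uqua`` or ``vst``.
    """

    values: pd.DataFrame
    group: pd.Series
    normalization_state: str = "raw"

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            dup = self.values.index[self.values.index.duplicated()][0]
            raise DataModelError(f"duplicate gene id: {dup!r}")
        if self.values.columns.duplicated().any():
            dup = self.values.columns[self.values.columns.duplicated()][0]
            raise DataModelError(f"duplicate sample id: {dup!r}")
        self.group = self.group.reindex(self.values.columns)
        if self.group.isna().any():
            missing = list(self.group.index[self.group.isna()])
            raise DataModelError(f"samples without group label: {missing}")
        arr = self.values.to_numpy()
        if not np.isfinite(arr).all():
            raise DataModelError("expression values must be finite")
        if self.normalization_state == "raw":
            if (arr < 0).any():
                raise DataModelError("raw counts must be non-negative")
            if not np.allclose(arr, np.round(arr)):
                raise DataModelError("raw counts must be integers")

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def group_columns(self, label: str) -> pd.DataFrame:
        """Columns belonging to one group label."""
        return self.values.loc[:, self.group == label]

    def require_groups(self, min_per_group: int = 2) -> None:
        """Validate that every group has at least ``min_per_group`` samples."""
        sizes = self.group.value_counts()
        small = sizes[sizes < min_per_group]
        if len(small):
            raise DataModelError(
                f"groups with fewer than {min_per_group} samples: "
                f"{dict(small)}"
            )

    def subset_genes(self, ids: Sequence[str]) -> "CountMatrix":
        sub = self.values.loc[list(ids)]
        return CountMatrix(sub, self.group.copy(), self.normalization_state)

    def with_values(self, values: pd.DataFrame, state: str) -> "CountMatrix":
        return CountMatrix(values, self.group.copy(), state)


def read_counts(path, group_map: Mapping[str, str]) -> CountMatrix:
    """Read a TSV count matrix (first column gene ids, header sample ids).

    ``group_map`` assigns each sample id a group label. Non-numeric cells and
    duplicated ids are hard errors; genes with all-zero rows are kept here and
    removed by :func:`lncnet.normalization.filter_nonzero`.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    bad = df.columns[~df.apply(lambda c: pd.to_numeric(c, errors="coerce").notna().all())]
    if len(bad):
        col = bad[0]
        row = df.index[pd.to_numeric(df[col], errors="coerce").isna()][0]
        raise DataModelError(f"non-numeric cell at gene {row!r}, sample {col!r}")
    df = df.astype(float)
    try:
        group = pd.Series({s: group_map[s] for s in df.columns})
    except KeyError as exc:
        raise DataModelError(f"sample {exc.args[0]!r} missing from group map") from None
    return CountMatrix(df, group, "raw")


def write_counts(cm: CountMatrix, path) -> None:
    out = cm.values
    if cm.normalization_state == "raw":
        out = out.astype(int)
    out.to_csv(path, sep="\t", index_label="gene_id")


# ---------------------------------------------------------------------------
# GeneAnnotation
# ---------------------------------------------------------------------------

ANNOTATION_COLUMNS = ["gene_id", "symbol", "biotype", "chrom", "start", "end", "strand"]


@dataclass
class GeneAnnotation:
    """Per-gene biotype and 1-based inclusive genomic interval."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in ANNOTATION_COLUMNS if c not in self.table.columns]
        if missing:
            raise DataModelError(f"annotation missing columns: {missing}")
        t = self.table
        if t["gene_id"].duplicated().any():
            dup = t.loc[t["gene_id"].duplicated(), "gene_id"].iloc[0]
            raise DataModelError(f"duplicate gene id in annotation: {dup!r}")
        if (t["biotype"].astype(str).str.len() == 0).any() or t["biotype"].isna().any():
            raise DataModelError("empty biotype in annotation")
        bad = t[t["start"] > t["end"]]
        if len(bad):
            raise DataModelError(
                f"start > end for gene {bad['gene_id'].iloc[0]!r}"
            )
        self.table = t.reset_index(drop=True)

    @property
    def gene_ids(self) -> pd.Index:
        return pd.Index(self.table["gene_id"])

    def intervals(self) -> pd.DataFrame:
        return self.table.set_index("gene_id")[["chrom", "start", "end", "strand"]]

    def biotype_of(self) -> pd.Series:
        return self.table.set_index("gene_id")["biotype"]


def read_annotation(path, dialect: str = "biomart_tsv") -> GeneAnnotation:
    """Read gene annotation from a BioMart-style TSV or a GTF.

    The GTF path keeps only ``gene`` features and reads the ``gene_id``,
    ``gene_name`` and ``gene_biotype`` attributes; coordinates come back on
    the 1-based inclusive scale either way.
    """
    if dialect == "biomart_tsv":
        df = pd.read_csv(path, sep="\t")
        rename = {
            "Gene stable ID": "gene_id",
            "Gene name": "symbol",
            "Gene type": "biotype",
            "Chromosome/scaffold name": "chrom",
            "Gene start (bp)": "start",
            "Gene end (bp)": "end",
            "Strand": "strand",
        }
        df = df.rename(columns=rename)
        missing = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
        if missing:
            raise DataModelError(f"annotation TSV missing columns: {missing}")
        df = df[ANNOTATION_COLUMNS].copy()
    elif dialect == "gtf":
        import pyranges

        pr = pyranges.read_gtf(path)
        df = pr.df
        df = df[df["Feature"] == "gene"].copy()
        if "gene_biotype" not in df.columns:
            raise DataModelError("GTF lacks gene_biotype attribute")
        if "gene_name" not in df.columns:
            df["gene_name"] = df["gene_id"]
        df = pd.DataFrame(
            {
                "gene_id": df["gene_id"],
                "symbol": df["gene_name"].fillna(df["gene_id"]),
                "biotype": df["gene_biotype"],
                "chrom": df["Chromosome"].astype(str),
                # pyranges is 0-based half-open internally
                "start": df["Start"].astype(int) + 1,
                "end": df["End"].astype(int),
                "strand": df["Strand"].astype(str),
            }
        )
    else:
        raise DataModelError(f"unknown annotation dialect: {dialect!r}")
    df["start"] = df["start"].astype(int)
    df["end"] = df["end"].astype(int)
    return GeneAnnotation(df)


def write_annotation(ann: GeneAnnotation, path) -> None:
    ann.table.to_csv(path, sep="\t", index=False)


def partition_by_biotype(
    ann: GeneAnnotation,
    lnc_biotypes: Iterable[str] = DEFAULT_LNC_BIOTYPES,
    pcg_biotypes: Iterable[str] = DEFAULT_PCG_BIOTYPES,
) -> tuple[list[str], list[str], pd.DataFrame]:
    """Split annotated genes into lncRNA and protein-coding id lists.

    Returns ``(lnc_ids, pcg_ids, summary)`` where ``summary`` counts each
    biotype class (lncRNA sub-biotypes individually, protein_coding, and a
    pooled ``other``) with its percentage of annotated genes.
    """
    lnc_set, pcg_set = set(lnc_biotypes), set(pcg_biotypes)
    bt = ann.table["biotype"]
    lnc_ids = list(ann.table.loc[bt.isin(lnc_set), "gene_id"])
    pcg_ids = list(ann.table.loc[bt.isin(pcg_set), "gene_id"])
    if not lnc_ids or not pcg_ids:
        warnings.warn("empty lncRNA or protein-coding partition", stacklevel=2)

    def klass(b: str) -> str:
        if b in lnc_set:
            return b
        if b in pcg_set:
            return "protein_coding"
        return "other"

    counts = bt.map(klass).value_counts()
    summary = pd.DataFrame(
        {
            "count": counts,
            "percent": 100.0 * counts / len(ann.table),
        }
    )
    summary.index.name = "class"
    return lnc_ids, pcg_ids, summary


# ---------------------------------------------------------------------------
# GeneSetCollection (GMT)
# ---------------------------------------------------------------------------

@dataclass
class GeneSetCollection:
    """Mapping of set id -> (name, members); members deduplicated, order kept."""

    sets: dict[str, tuple[str, list[str]]] = field(default_factory=dict)
    universe: list[str] | None = None

    def __post_init__(self) -> None:
        clean: dict[str, tuple[str, list[str]]] = {}
        for sid, (name, members) in self.sets.items():
            members = list(dict.fromkeys(members))
            if not members:
                raise DataModelError(f"gene set {sid!r} is empty")
            clean[sid] = (name, members)
        self.sets = clean

    def __len__(self) -> int:
        return len(self.sets)

    def members(self, sid: str) -> list[str]:
        return self.sets[sid][1]

    def ids(self) -> list[str]:
        return list(self.sets)


def read_gmt(path) -> GeneSetCollection:
    """Parse a GMT file (``set_id TAB name TAB member...`` per line)."""
    sets: dict[str, tuple[str, list[str]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                warnings.warn(
                    f"skipping GMT line {lineno}: no members", stacklevel=2
                )
                continue
            sid, name, members = parts[0], parts[1], [m for m in parts[2:] if m]
            if not members:
                warnings.warn(
                    f"skipping GMT line {lineno}: no members", stacklevel=2
                )
                continue
            sets[sid] = (name, members)
    return GeneSetCollection(sets)


def write_gmt(coll: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for sid, (name, members) in coll.sets.items():
            fh.write("\t".join([sid, name, *members]) + "\n")


# ---------------------------------------------------------------------------
# DETable helpers and generic writers
# ---------------------------------------------------------------------------

DE_COLUMNS = ["gene_id", "log2fc", "padj", "mean_healthy", "mean_tumour", "status"]


def assign_de_status(df: pd.DataFrame, t_log2fc: float = 1.5, alpha: float = 0.05) -> pd.DataFrame:
    """Attach ``status`` in {up, down, not_de} by |log2FC| and padj thresholds."""
    if ((df["padj"] < 0) | (df["padj"] > 1)).any():
        bad = df.loc[(df["padj"] < 0) | (df["padj"] > 1)].index[0]
        raise DataModelError(f"padj outside [0,1] for gene {bad!r}")
    status = np.where(
        (df["log2fc"] >= t_log2fc) & (df["padj"] <= alpha),
        "up",
        np.where((df["log2fc"] <= -t_log2fc) & (df["padj"] <= alpha), "down", "not_de"),
    )
    out = df.copy()
    out["status"] = status
    return out


def write_edges(edges: pd.DataFrame, path) -> None:
    """Write the bipartite edge list as TSV."""
    edges.to_csv(path, sep="\t", index=False)


def write_graphml(graph, path) -> None:
    import networkx as nx

    nx.write_graphml(graph, path)


def write_report(obj, path) -> None:
    """JSON-serialize a run report (dataclasses, numpy scalars ok)."""

    def default(o):
        if dataclasses.is_dataclass(o) and not isinstance(o, type):
            return dataclasses.asdict(o)
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, (np.ndarray,)):
            return o.tolist()
        if isinstance(o, (set, frozenset)):
            return sorted(o)
        if isinstance(o, pd.DataFrame):
            return json.loads(o.to_json(orient="records"))
        if isinstance(o, pd.Series):
            return o.to_dict()
        raise TypeError(f"not JSON serializable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=default)
        fh.write("\n")
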