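import numpy as np
import pandas as pd
import pytest

from lncnet.data_model import (
    DataModelError,
    GeneAnnotation,
    GeneSetCollection,
    partition_by_biotype,
    read_annotation,
    read_counts,
    read_gmt,
    write_counts,
    write_edges,
    write_gmt,
)


@pytest.fixture
def group_map():
    return {f"S{i}": ("healthy" if i < 3 else "tumour") for i in range(6)}


class TestCounts:
    def test_round_trip_identity(self, tmp_path, group_map):
        rng = np.random.default_rng(7)
        for shape in [(3, 6), (20, 6), (1, 6)]:
            df = pd.DataFrame(
                rng.integers(0, 1000, size=shape),
                index=[f"g{i}" for i in range(shape[0])],
                columns=[f"S{i}" for i in range(shape[1])],
            )
            p = tmp_path / "c.tsv"
            df.to_csv(p, sep="\t", index_label="gene_id")
            cm = read_counts(p, group_map)
            assert cm.n_genes == shape[0] and cm.n_samples == 6
            out = tmp_path / "c2.tsv"
            write_counts(cm, out)
            cm2 = read_counts(out, group_map)
            pd.testing.assert_frame_equal(cm.values, cm2.values)

    def test_duplicate_gene_id_named_in_error(self, tmp_path, group_map):
        p = tmp_path / "dup.tsv"
        p.write_text("gene_id\t" + "\t".join(group_map) + "\n"
                     + "gX\t1\t2\t3\t4\t5\t6\n" + "gX\t1\t2\t3\t4\t5\t6\n")
        with pytest.raises(DataModelError, match="gX"):
            read_counts(p, group_map)

    def test_non_numeric_cell_reports_location(self, tmp_path, group_map):
        p = tmp_path / "bad.tsv"
        p.write_text("gene_id\t" + "\t".join(group_map) + "\n"
                     + "g1\t1\t2\toops\t4\t5\t6\n")
        with pytest.raises(DataModelError, match="g1"):
            read_counts(p, group_map)


class TestAnnotation:
    BIOMART_HEADER = "gene_id\tsymbol\tbiotype\tchrom\tstart\tend\tstrand\n"

    def test_biomart_single_gene(self, tmp_path):
        p = tmp_path / "ann.tsv"
        p.write_text(self.BIOMART_HEADER + "G1\tFOO\tlincRNA\tchr2\t100\t200\t+\n")
        ann = read_annotation(p, "biomart_tsv")
        rec = ann.table.iloc[0]
        assert (rec["start"], rec["end"], rec["chrom"]) == (100, 200, "chr2")

    def test_gtf_equals_biomart(self, tmp_path):
        rng = np.random.default_rng(3)
        rows = []
        for i in range(10):
            start = int(rng.integers(1, 10_000))
            end = start + int(rng.integers(10, 5_000))
            rows.append((f"G{i}", f"SYM{i}", "protein_coding" if i % 2 else "lincRNA",
                         f"chr{i % 3 + 1}", start, end, "+" if i % 2 else "-"))
        tsv = tmp_path / "a.tsv"
        tsv.write_text(self.BIOMART_HEADER + "".join(
            "\t".join(map(str, r)) + "\n" for r in rows))
        gtf = tmp_path / "a.gtf"
        gtf.write_text("".join(
            f'{r[3]}\tsrc\tgene\t{r[4]}\t{r[5]}\t.\t{r[6]}\t.\t'
            f'gene_id "{r[0]}"; gene_name "{r[1]}"; gene_biotype "{r[2]}";\n'
            for r in rows))
        a = read_annotation(tsv, "biomart_tsv").table.sort_values("gene_id").reset_index(drop=True)
        b = read_annotation(gtf, "gtf").table.sort_values("gene_id").reset_index(drop=True)
        pd.testing.assert_frame_equal(a, b[a.columns])

    def test_start_after_end_rejected(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text(self.BIOMART_HEADER + "G9\tX\tlincRNA\tchr1\t201\t200\t+\n")
        with pytest.raises(DataModelError, match="G9"):
            read_annotation(p, "biomart_tsv")


class TestBiotypePartition:
    def _ann(self, biotypes):
        return GeneAnnotation(pd.DataFrame({
            "gene_id": [f"G{i}" for i in range(len(biotypes))],
            "symbol": [f"S{i}" for i in range(len(biotypes))],
            "biotype": biotypes,
            "chrom": "chr1",
            "start": np.arange(len(biotypes)) * 1000 + 1,
            "end": np.arange(len(biotypes)) * 1000 + 500,
            "strand": "+",
        }))

    def test_simple_percentages(self):
        ann = self._ann(["protein_coding"] * 7 + ["lincRNA"] * 3)
        lnc, pcg, summary = partition_by_biotype(ann)
        assert len(lnc) == 3 and len(pcg) == 7
        assert summary.loc["protein_coding", "percent"] == pytest.approx(70.0)
        assert summary.loc["lincRNA", "percent"] == pytest.approx(30.0)

    def test_unknown_biotype_counts_as_other(self):
        ann = self._ann(["protein_coding", "weird_class"])
        with pytest.warns(UserWarning, match="empty"):
            lnc, pcg, summary = partition_by_biotype(ann)
        assert summary.loc["other", "count"] == 1
        assert set(lnc) == set() and len(pcg) == 1

    def test_partition_is_disjoint_cover(self, default_sim):
        ann = default_sim.annotation
        lnc, pcg, summary = partition_by_biotype(ann)
        assert not set(lnc) & set(pcg)
        assert summary["count"].sum() == len(ann.table)
        # generator proportions recovered within rounding
        assert summary.loc["protein_coding", "percent"] == pytest.approx(73.0, abs=0.5)
        lnc_pct = sum(summary.loc[c, "percent"] for c in summary.index
                      if c not in ("protein_coding", "other"))
        assert lnc_pct == pytest.approx(13.6, abs=0.5)


class TestGeneSets:
    def test_gmt_round_trip(self, tmp_path):
        p = tmp_path / "x.gmt"
        p.write_text("S1\tfirst set\ta\tb\tc\nS2\tsecond\td\te\tf\n")
        coll = read_gmt(p)
        assert len(coll) == 2 and coll.members("S2") == ["d", "e", "f"]
        out = tmp_path / "y.gmt"
        write_gmt(coll, out)
        assert read_gmt(out).sets == coll.sets

    def test_empty_set_line_skipped_with_warning(self, tmp_path):
        p = tmp_path / "x.gmt"
        p.write_text("S1\tok\ta\tb\nS2\tempty\n")
        with pytest.warns(UserWarning, match="no members"):
            coll = read_gmt(p)
        assert coll.ids() == ["S1"]

    def test_empty_set_rejected(self):
        with pytest.raises(DataModelError, match="empty"):
            GeneSetCollection({"S1": ("x", [])})

    def test_edge_file_row_count(self, tmp_path, default_run):
        _, report = default_run
        p = tmp_path / "edges.tsv"
        write_edges(report.network.edges, p)
        assert len(pd.read_csv(p, sep="\t")) == len(report.network.edges)
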