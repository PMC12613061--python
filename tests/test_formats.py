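import numpy as np
import pytest

from regumirror.formats import (
    FormatError,
    GenomicInterval,
    InvalidSymbolError,
    NarrowPeakRecord,
    OrthologMap,
    PFM,
    SchemaError,
    SequenceStore,
    harmonize_symbol,
    read_bed_intervals,
    read_deg_table,
    read_gmt,
    read_jaspar_pfm,
    read_narrowpeak,
    read_ortholog_map,
    read_tss,
    write_deg_table,
    write_gmt,
    write_narrowpeak,
    write_tss_bed6,
)


@pytest.mark.parametrize(
    "raw,expected",
    [("Spp1", "SPP1"), ("SRF", "SRF"), (" Nexn ", "NEXN"), ("sox9", "SOX9")],
)
def test_harmonize_symbol(raw, expected):
    assert harmonize_symbol(raw) == expected


@pytest.mark.parametrize("raw", ["", "   ", "\t"])
def test_harmonize_rejects_blank(raw):
    with pytest.raises(InvalidSymbolError):
        harmonize_symbol(raw)


class TestDEGTable:
    def test_duplicates_keep_smallest_padj(self, tmp_path):
        p = tmp_path / "d.tsv"
        p.write_text(
            "gene\tlog2fc\tpadj\nSpp1\t1.0\t0.01\nSRF\t-0.5\t0.2\nSPP1\t0.9\t0.04\n"
        )
        t = read_deg_table(p, dataset_id="x")
        assert len(t) == 2
        assert t.get("SPP1").padj == 0.01

    def test_missing_padj_retained(self, tmp_path):
        p = tmp_path / "d.tsv"
        p.write_text("gene\tlog2fc\tpadj\nSRF\t-0.5\tNA\n")
        t = read_deg_table(p)
        assert t.get("SRF").padj is None

    def test_empty_table_allowed(self, tmp_path):
        p = tmp_path / "d.tsv"
        p.write_text("gene\tlog2fc\tpadj\n")
        assert len(read_deg_table(p)) == 0

    def test_missing_column_is_schema_error(self, tmp_path):
        p = tmp_path / "d.tsv"
        p.write_text("symbol\tlfc\tq\nSRF\t1\t0.1\n")
        with pytest.raises(SchemaError):
            read_deg_table(p)

    def test_bad_numeric_reports_line(self, tmp_path):
        p = tmp_path / "d.tsv"
        p.write_text("gene\tlog2fc\tpadj\nSRF\toops\t0.1\n")
        with pytest.raises(FormatError, match=":2"):
            read_deg_table(p)

    def test_custom_column_map(self, tmp_path):
        p = tmp_path / "d.csv"
        p.write_text("symbol,lfc,q\nNexn,-1.2,0.001\n")
        t = read_deg_table(p, column_map={"gene": "symbol", "log2fc": "lfc", "padj": "q"})
        assert t.get("NEXN").log2fc == -1.2

    def test_roundtrip(self, tmp_path, rng):
        genes = [f"G{i}" for i in range(50)]
        rows = "\n".join(
            f"{g}\t{rng.normal():.6g}\t{'NA' if i % 7 == 0 else rng.uniform()}"
            for i, g in enumerate(genes)
        )
        p = tmp_path / "a.tsv"
        p.write_text("gene\tlog2fc\tpadj\n" + rows + "\n")
        t = read_deg_table(p, dataset_id="a")
        q = tmp_path / "b.tsv"
        write_deg_table(t, q)
        t2 = read_deg_table(q, dataset_id="a")
        assert t.records == t2.records


class TestNarrowPeak:
    def test_parse_fields(self, tmp_path):
        p = tmp_path / "a.narrowPeak"
        p.write_text("chr1\t100\t600\tp1\t300\t.\t8.5\t40.0\t30.0\t250\n")
        (rec,) = read_narrowpeak(p)
        assert rec.interval == GenomicInterval("chr1", 100, 600, ".")
        assert (rec.score, rec.neglog10_q, rec.summit_offset) == (300, 30.0, 250)

    def test_sentinels_become_none(self, tmp_path):
        p = tmp_path / "a.narrowPeak"
        p.write_text("chr1\t100\t600\tp1\t300\t.\t8.5\t-1\t-1\t-1\n")
        (rec,) = read_narrowpeak(p)
        assert rec.neglog10_p is None and rec.neglog10_q is None
        assert rec.summit_offset is None

    @pytest.mark.parametrize(
        "line",
        ["chr1\t100\t600\tp1\t300\t.\t8.5\t40.0", "chr1\t600\t100\tp1\t300\t.\t1\t-1\t-1\t-1"],
    )
    def test_malformed_rejected(self, tmp_path, line):
        p = tmp_path / "a.narrowPeak"
        p.write_text(line + "\n")
        with pytest.raises(FormatError):
            read_narrowpeak(p)

    def test_random_roundtrip(self, tmp_path, rng):
        peaks = []
        for i in range(100):
            start = int(rng.integers(0, 10_000))
            length = int(rng.integers(1, 500))
            peaks.append(
                NarrowPeakRecord(
                    interval=GenomicInterval(f"chr{int(rng.integers(1, 4))}", start, start + length),
                    name=f"p{i}",
                    score=int(rng.integers(0, 1500)),
                    signal_value=float(np.round(rng.uniform(0, 100), 4)),
                    neglog10_p=None if rng.random() < 0.3 else float(np.round(rng.uniform(0, 80), 3)),
                    neglog10_q=None if rng.random() < 0.3 else float(np.round(rng.uniform(0, 60), 3)),
                    summit_offset=None if rng.random() < 0.3 else int(rng.integers(0, length)),
                )
            )
        path = tmp_path / "r.narrowPeak"
        write_narrowpeak(peaks, path)
        assert read_narrowpeak(path) == peaks


class TestTSS:
    def test_gtf_plus_strand(self, tmp_path):
        p = tmp_path / "a.gtf"
        p.write_text('chr1\tsrc\tgene\t1001\t2000\t.\t+\t.\tgene_name "Srf";\n')
        (rec,) = read_tss(p, format="gtf")
        assert (rec.gene_symbol, rec.tss, rec.strand) == ("SRF", 1000, "+")

    def test_gtf_minus_strand(self, tmp_path):
        p = tmp_path / "a.gtf"
        p.write_text('chr1\tsrc\tgene\t1001\t2000\t.\t-\t.\tgene_name "Srf";\n')
        (rec,) = read_tss(p, format="gtf")
        assert rec.tss == 1999

    def test_bed6_minus_strand(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("chr2\t500\t900\tgeneX\t0\t-\n")
        (rec,) = read_tss(p, format="bed6")
        assert (rec.gene_symbol, rec.tss) == ("GENEX", 899)

    def test_unknown_format_tag(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("chr1\t0\t1\tg\t0\t+\n")
        with pytest.raises(ValueError, match="format"):
            read_tss(p, format="gff3")

    def test_strandless_feature_rejected(self, tmp_path):
        p = tmp_path / "a.gtf"
        p.write_text('chr1\tsrc\tgene\t1\t100\t.\t.\t.\tgene_name "X";\n')
        with pytest.raises(FormatError):
            read_tss(p, format="gtf")

    def test_gtf_to_bed6_idempotent(self, tmp_path):
        gtf = tmp_path / "a.gtf"
        gtf.write_text(
            'chr1\ts\tgene\t5001\t7000\t.\t+\t.\tgene_name "A";\n'
            'chr1\ts\tgene\t9001\t9500\t.\t-\t.\tgene_name "B";\n'
        )
        first = read_tss(gtf, format="gtf")
        bed = tmp_path / "a.bed"
        write_tss_bed6(first, bed)
        assert read_tss(bed, format="bed6") == first


class TestJaspar:
    def test_consensus_and_width(self, tmp_path):
        p = tmp_path / "m.jaspar"
        p.write_text(
            ">MA0001 TEADX\n"
            "A [ 1 2 10 10 1 2 ]\n"
            "C [ 1 2 0 0 1 2 ]\n"
            "G [ 8 6 0 0 1 6 ]\n"
            "T [ 0 0 0 0 7 0 ]\n"
        )
        (pfm,) = read_jaspar_pfm(p)
        assert pfm.width == 6
        assert pfm.consensus == "GGAATG"

    def test_two_motifs_in_order(self, tmp_path):
        p = tmp_path / "m.jaspar"
        p.write_text(
            ">M1 A\nA [1 1 1 1]\nC [2 1 1 1]\nG [1 1 1 1]\nT [1 1 1 1]\n"
            ">M2 B\nA [1 1 1 1]\nC [1 1 1 1]\nG [3 1 1 1]\nT [1 1 1 1]\n"
        )
        pfms = read_jaspar_pfm(p)
        assert [m.motif_id for m in pfms] == ["M1", "M2"]

    def test_name_defaults_to_id(self, tmp_path):
        p = tmp_path / "m.jaspar"
        p.write_text(">M9\nA [1 1 1 1]\nC [1 1 1 1]\nG [1 1 1 1]\nT [1 1 1 1]\n")
        (pfm,) = read_jaspar_pfm(p)
        assert pfm.name == "M9"

    def test_unequal_widths_rejected(self, tmp_path):
        p = tmp_path / "m.jaspar"
        p.write_text(">M X\nA [1 2 3]\nC [1 2]\nG [1 2 3]\nT [1 2 3]\n")
        with pytest.raises(FormatError):
            read_jaspar_pfm(p)

    def test_negative_counts_rejected(self, tmp_path):
        p = tmp_path / "m.jaspar"
        p.write_text(">M X\nA [1 -2 1 1]\nC [1 2 1 1]\nG [1 2 1 1]\nT [1 2 1 1]\n")
        with pytest.raises(FormatError):
            read_jaspar_pfm(p)


class TestGMT:
    def test_read_and_harmonize(self, tmp_path):
        p = tmp_path / "s.gmt"
        p.write_text("T1\tdesc\tSox9\tCOL2A1\tSox9\nT2\tdesc\tACTA2\tMYH11\n")
        c = read_gmt(p)
        assert len(c) == 2
        assert c.members("T1") == {"SOX9", "COL2A1"}

    def test_duplicate_term_rejected(self, tmp_path):
        p = tmp_path / "s.gmt"
        p.write_text("T1\td\tA1\nT1\td\tB1\n")
        with pytest.raises(FormatError):
            read_gmt(p)

    def test_empty_set_dropped(self, tmp_path):
        p = tmp_path / "s.gmt"
        p.write_text("T1\td\tA1\nT2\td\n")
        assert read_gmt(p).term_ids() == ["T1"]

    def test_roundtrip(self, tmp_path, rng):
        sets = {
            f"T{i}": ("d", frozenset(f"G{int(g)}" for g in rng.integers(0, 200, 15)))
            for i in range(20)
        }
        from regumirror.formats import GeneSetCollection

        c = GeneSetCollection(sets=sets)
        path = tmp_path / "r.gmt"
        write_gmt(c, path)
        c2 = read_gmt(path)
        assert {t: c2.members(t) for t in c2.term_ids()} == {
            t: m for t, (_, m) in sets.items()
        }


class TestOrthologs:
    def test_pairs_and_dedup(self, tmp_path):
        p = tmp_path / "o.tsv"
        p.write_text(
            "human_symbol\tmouse_symbol\nSRF\tSrf\nNEXN\tNexn\nSRF\tSrf\n"
        )
        omap = read_ortholog_map(p)
        assert omap.pairs == [("SRF", "SRF"), ("NEXN", "NEXN")]

    def test_one_to_many_retained(self, tmp_path):
        p = tmp_path / "o.tsv"
        p.write_text("human_symbol\tmouse_symbol\nFGFR2\tFgfr2\nFGFR2\tFgfr2b\n")
        omap = read_ortholog_map(p)
        assert len(omap) == 2
        assert omap.mouse_for_human()["FGFR2"] == ["FGFR2", "FGFR2B"]

    def test_missing_column(self, tmp_path):
        p = tmp_path / "o.tsv"
        p.write_text("a\tb\nX\tY\n")
        with pytest.raises(SchemaError):
            read_ortholog_map(p)


class TestSequenceStore:
    def test_fetch_and_bounds(self, tmp_path):
        store = SequenceStore({"chr1": "acgtACGT"})
        assert store.fetch("chr1", 0, 4) == "ACGT"
        with pytest.raises(IndexError):
            store.fetch("chr1", 5, 20)
        with pytest.raises(KeyError):
            store.fetch("chrX", 0, 1)

    def test_fasta_roundtrip(self, tmp_path):
        store = SequenceStore({"c1": "ACGTN" * 10, "c2": "GGAATG" * 5})
        path = tmp_path / "g.fa"
        store.to_fasta(path)
        back = SequenceStore.from_fasta(path)
        assert back.fetch("c2", 0, 6) == "GGAATG"
        assert back.chrom_length("c1") == 50


def test_bed_intervals_half_open(tmp_path):
    p = tmp_path / "b.bed"
    p.write_text("chr1\t10\t20\nchr1\t30\t40\t.\t0\t-\n")
    ivs = read_bed_intervals(p)
    assert ivs[0] == GenomicInterval("chr1", 10, 20, ".")
    assert ivs[1].strand == "-"
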