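"""Annotation parsing, filtering, coordinate arithmetic and assignment."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nmdsplice import annotation
from nmdsplice.annotation import (
    AnnotationError,
    Gene,
    GenomicInterval,
    Intron,
    Transcript,
    assign_secondary,
    filter_genes,
    parse_annotation,
    write_gtf,
)
from nmdsplice.synthetic import all_fixture_genes

TOY_GTF = """\
chr1\tsrc\ttranscript\t101\t900\t.\t+\t.\tgene_id "G1"; transcript_id "T1"; transcript_type "protein_coding";
chr1\tsrc\texon\t101\t200\t.\t+\t.\tgene_id "G1"; transcript_id "T1";
chr1\tsrc\texon\t301\t400\t.\t+\t.\tgene_id "G1"; transcript_id "T1";
chr1\tsrc\texon\t501\t900\t.\t+\t.\tgene_id "G1"; transcript_id "T1";
chr1\tsrc\tstart_codon\t101\t103\t.\t+\t.\tgene_id "G1"; transcript_id "T1";
chr1\tsrc\tstop_codon\t601\t603\t.\t+\t.\tgene_id "G1"; transcript_id "T1";
"""

TOY_GFF3 = TOY_GTF.replace('gene_id "G1"; transcript_id "T1"; transcript_type "protein_coding";',
                           "gene_id=G1;transcript_id=T1;transcript_type=protein_coding").replace(
    'gene_id "G1"; transcript_id "T1";', "gene_id=G1;transcript_id=T1")


def _write(tmp_path, text, name="toy.gtf"):
    p = tmp_path / name
    p.write_text(text)
    return str(p)


class TestParse:
    def test_toy_gtf(self, tmp_path):
        genes = parse_annotation(_write(tmp_path, TOY_GTF))
        assert set(genes) == {"G1"}
        tx = genes["G1"].transcripts["T1"]
        assert len(tx.exons) == 3
        assert [(i.start, i.end) for i in tx.introns()] == [(200, 300), (400, 500)]
        assert tx.start_codon == GenomicInterval("chr1", 100, 103, "+")
        assert tx.biotype == "protein_coding"

    def test_gff3_dialect_equivalent(self, tmp_path):
        g1 = parse_annotation(_write(tmp_path, TOY_GTF, "a.gtf"))
        g2 = parse_annotation(_write(tmp_path, TOY_GFF3, "b.gff3"), dialect="gff")
        t1, t2 = g1["G1"].transcripts["T1"], g2["G1"].transcripts["T1"]
        assert t1.exons == t2.exons
        assert t1.start_codon == t2.start_codon
        assert t1.stop_codon == t2.stop_codon

    def test_bad_coordinates_rejected_record_level(self, tmp_path):
        bad = TOY_GTF + 'chr1\tsrc\texon\t800\t700\t.\t+\t.\tgene_id "G1"; transcript_id "T1";\n'
        genes = parse_annotation(_write(tmp_path, bad))
        # the malformed exon is dropped, the rest of the gene is intact
        assert len(genes["G1"].transcripts["T1"].exons) == 3

    def test_missing_transcript_id_skipped(self, tmp_path):
        bad = TOY_GTF + 'chr1\tsrc\texon\t950\t990\t.\t+\t.\tgene_id "G1";\n'
        genes = parse_annotation(_write(tmp_path, bad))
        assert len(genes["G1"].transcripts["T1"].exons) == 3

    def test_exon_order_irrelevant(self, tmp_path):
        lines = TOY_GTF.strip().split("\n")
        shuffled = "\n".join([lines[0], lines[3], lines[1], lines[2]] + lines[4:]) + "\n"
        g1 = parse_annotation(_write(tmp_path, TOY_GTF, "a.gtf"))
        g2 = parse_annotation(_write(tmp_path, shuffled, "b.gtf"))
        assert (
            g1["G1"].transcripts["T1"].introns()
            == g2["G1"].transcripts["T1"].introns()
        )

    @pytest.mark.parametrize("name", ["PE", "MXE", "hps1_like", "utr3_ir"])
    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_write_parse_roundtrip(self, tmp_path, name, strand):
        fixtures = all_fixture_genes(strand)
        gene, _ = fixtures[name]
        path = str(tmp_path / "rt.gtf")
        write_gtf([gene], path)
        back = parse_annotation(path)[gene.gene_id]
        assert set(back.transcripts) == set(gene.transcripts)
        for tid, tx in gene.transcripts.items():
            b = back.transcripts[tid]
            assert b.exons == tx.exons
            assert b.start_codon == tx.start_codon
            assert b.stop_codon == tx.stop_codon
            assert b.biotype == tx.biotype


class TestCoordinates:
    def _tx(self, strand="+"):
        t = Transcript("T", "G", "c", strand)
        t.exons = [
            GenomicInterval("c", 0, 100, strand),
            GenomicInterval("c", 200, 300, strand),
        ]
        t.finalize()
        return t

    def test_first_base_and_interior(self):
        t = self._tx()
        assert t.genomic_to_mrna(0) == 0
        assert t.genomic_to_mrna(250) == 150

    def test_minus_strand_mirror(self):
        t = self._tx("-")
        # 5'-most base on the − strand is position 299
        assert t.genomic_to_mrna(299) == 0
        # the mirror image of position 250 (namely 49) maps to offset 150
        assert t.genomic_to_mrna(49) == 150

    def test_intronic_position_rejected(self):
        with pytest.raises(AnnotationError):
            self._tx().genomic_to_mrna(150)

    @settings(max_examples=60, derandomize=True)
    @given(st.integers(min_value=0, max_value=199))
    def test_roundtrip(self, offset):
        for strand in "+-":
            t = self._tx(strand)
            assert t.genomic_to_mrna(t.mrna_to_genomic(offset)) == offset

    def test_introns_minus_strand_order(self):
        t = Transcript("T", "G", "c", "-")
        t.exons = [GenomicInterval("c", s, e, "-") for s, e in
                   [(0, 100), (200, 300), (400, 500)]]
        t.finalize()
        ii = t.introns()
        # ordered 5'→3' along the − strand: the high-coordinate gap first
        assert [(i.start, i.end) for i in ii] == [(300, 400), (100, 200)]
        assert ii[0].donor == 400 and ii[0].acceptor == 300

    def test_single_exon_no_introns(self):
        t = Transcript("T", "G", "c", "+")
        t.exons = [GenomicInterval("c", 0, 100, "+")]
        t.finalize()
        assert t.introns() == []

    def test_gtf_conversion_roundtrips(self):
        iv = GenomicInterval.from_gtf("c", 101, 200, "+")
        assert (iv.start, iv.end) == (100, 200)
        assert iv.to_gtf() == (101, 200)


def _mk_tx(tid, gid, exons, strand="+", chrom="c", biotype="", start=None, stop=None):
    t = Transcript(tid, gid, chrom, strand, biotype=biotype)
    t.exons = [GenomicInterval(chrom, s, e, strand) for s, e in exons]
    if start:
        t.start_codon = GenomicInterval(chrom, *start, strand)
    if stop:
        t.stop_codon = GenomicInterval(chrom, *stop, strand)
    t.finalize()
    return t


def _mk_gene(gid, txs, chrom="c", strand="+"):
    g = Gene(gid, chrom, strand)
    for t in txs:
        g.transcripts[t.transcript_id] = t
    return g


class TestFilterGenes:
    def _gene(self, with_nmdt=True, with_coding=True):
        txs = []
        if with_coding:
            t = _mk_tx("C", "G", [(0, 100), (200, 320)], biotype="protein_coding",
                       start=(10, 13), stop=(300, 303))
            t.is_nmdt = False
            txs.append(t)
        if with_nmdt:
            t = _mk_tx("N", "G", [(0, 100), (200, 300), (400, 500)],
                       biotype="nonsense_mediated_decay", start=(10, 13), stop=(20, 23))
            t.is_nmdt = True
            txs.append(t)
        return _mk_gene("G", txs)

    def test_gene_with_both_retained(self):
        assert set(filter_genes({"G": self._gene()})) == {"G"}

    def test_gene_without_nmdt_dropped(self):
        assert filter_genes({"G": self._gene(with_nmdt=False)}) == {}

    def test_transcript_without_stop_dropped_first(self):
        g = self._gene()
        g.transcripts["N"].stop_codon = None
        # the NMDT loses its stop codon, so the gene loses NMDT status too
        assert filter_genes({"G": g}) == {}


class TestAssignSecondary:
    def _genes(self):
        a = _mk_tx("A1", "GA", [(0, 100), (200, 300), (400, 500), (600, 700)])
        b = _mk_tx("B1", "GB", [(5000, 5100), (5200, 5300)])
        return {"GA": _mk_gene("GA", [a]), "GB": _mk_gene("GB", [b])}

    def test_max_shared_introns_wins(self):
        genes = self._genes()
        sec = _mk_tx("S", "", [(0, 100), (200, 300), (400, 500), (600, 700)])
        left = assign_secondary(genes, [sec])
        assert left == []
        assert "S" in genes["GA"].transcripts
        assert sec.gene_id == "GA"

    def test_overlap_below_half_unassigned(self):
        genes = self._genes()
        # 100 of 250 exonic bases overlap GA (40%), no shared introns
        sec = _mk_tx("S", "", [(50, 150), (1000, 1150)])
        left = assign_secondary(genes, [sec])
        assert [t.transcript_id for t in left] == ["S"]

    def test_tie_broken_by_overlap_fraction(self):
        a = _mk_tx("A1", "GA", [(0, 100), (200, 300)])
        b = _mk_tx("B1", "GB", [(0, 100), (200, 250)])
        genes = {"GA": _mk_gene("GA", [a]), "GB": _mk_gene("GB", [b])}
        sec = _mk_tx("S", "", [(0, 100), (200, 300)])  # same introns? none shared
        sec2 = _mk_tx("S", "", [(10, 90), (210, 290)])  # no shared introns at all
        assign_secondary(genes, [sec2])
        # full overlap with GA's span (100%) beats GB (some bases uncovered)
        assert "S" in genes["GA"].transcripts

    def test_never_cross_strand(self):
        genes = self._genes()
        sec = _mk_tx("S", "", [(0, 100), (200, 300)], strand="-")
        left = assign_secondary(genes, [sec])
        assert [t.transcript_id for t in left] == ["S"]
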