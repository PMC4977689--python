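"""Feature model invariants and GFF3/FASTA/TSV round trips."""

from __future__ import annotations

import pytest

from droughtnc.annotation import (
    DegradomeTag,
    Gff3ParseError,
    MatureMiRNA,
    TranscriptModel,
    as_rna,
    read_counts_tsv,
    read_fasta,
    read_gff3,
    read_mirna_table,
    revcomp_rna,
    write_fasta,
    write_gff3,
    write_mirna_table,
)


def make_transcript(**kw):
    base = dict(
        id="t1", chrom="chr1", start=100, end=400, strand="+",
        exons=((100, 200), (300, 400)), biotype="coding",
    )
    base.update(kw)
    return TranscriptModel(**base)


class TestTranscriptModel:
    def test_spliced_length_sums_exons(self):
        assert make_transcript().length_nt == 202

    def test_five_and_three_prime_follow_strand(self):
        plus = make_transcript()
        minus = make_transcript(strand="-")
        assert (plus.five_prime, plus.three_prime) == (100, 400)
        assert (minus.five_prime, minus.three_prime) == (400, 100)

    def test_introns_between_exons(self):
        assert make_transcript().introns() == ((201, 299),)

    @pytest.mark.parametrize(
        "kw",
        [
            dict(start=500),  # start > end
            dict(exons=((100, 200), (150, 400))),  # overlapping exons
            dict(exons=((300, 400), (100, 200))),  # unsorted exons
            dict(exons=((50, 200),)),  # exon outside span
            dict(exons=((200, 100),)),  # exon end < start
            dict(strand="?"),
            dict(biotype="tRNA"),
        ],
    )
    def test_invariant_violations_raise(self, kw):
        with pytest.raises(ValueError):
            make_transcript(**kw)


class TestGff3:
    def test_transcript_with_two_exons(self, tmp_path):
        gff = tmp_path / "a.gff3"
        gff.write_text(
            "##gff-version 3\n"
            "chr1\tx\tmRNA\t100\t400\t.\t+\t.\tID=t1\n"
            "chr1\tx\texon\t100\t200\t.\t+\t.\tParent=t1\n"
            "chr1\tx\texon\t300\t400\t.\t+\t.\tParent=t1\n"
        )
        (t,) = read_gff3(gff)
        assert t.exons == ((100, 200), (300, 400))
        assert t.length_nt == 202

    def test_empty_file_gives_empty_list(self, tmp_path):
        gff = tmp_path / "empty.gff3"
        gff.write_text("")
        assert read_gff3(gff) == []

    def test_feature_without_exons_gets_full_span(self, tmp_path):
        gff = tmp_path / "a.gff3"
        gff.write_text("chr1\tx\tpre_miRNA\t10\t150\t.\t-\t.\tID=p1\n")
        (t,) = read_gff3(gff)
        assert t.exons == ((10, 150),)
        assert t.biotype == "pre_miRNA"

    def test_exon_end_before_start_names_line(self, tmp_path):
        gff = tmp_path / "a.gff3"
        gff.write_text(
            "chr1\tx\tmRNA\t100\t400\t.\t+\t.\tID=t1\n"
            "chr1\tx\texon\t200\t100\t.\t+\t.\tParent=t1\n"
        )
        with pytest.raises(Gff3ParseError, match="line 2"):
            read_gff3(gff)

    def test_unknown_strand_symbol_rejected(self, tmp_path):
        gff = tmp_path / "a.gff3"
        gff.write_text("chr1\tx\tmRNA\t100\t400\t.\t*\t.\tID=t1\n")
        with pytest.raises(Gff3ParseError, match="strand"):
            read_gff3(gff)

    def test_round_trip_preserves_feature_set(self, tmp_path):
        transcripts = [
            make_transcript(),
            make_transcript(id="t2", strand="-", biotype="lncRNA",
                            exons=((100, 400),)),
            make_transcript(id="p1", start=500, end=640, biotype="pre_miRNA",
                            exons=((500, 640),)),
        ]
        path = tmp_path / "rt.gff3"
        write_gff3(transcripts, path)
        assert read_gff3(path) == transcripts


class TestMiRNATable:
    def test_3to5_input_is_reversed_not_complemented(self, tmp_path):
        path = tmp_path / "m.tsv"
        path.write_text(
            "id\tsequence\torientation\tprecursor_id\tarm\n"
            "miR-399k\tGCCCCGUUUAAAGGAAACCGU\t3to5\tpre-miR399k\tunspecified\n"
        )
        (m,) = read_mirna_table(path)
        assert m.sequence == "UGCCAAAGGAAAUUUGCCCCG"

    def test_reading_reversed_5to3_matches_3to5(self, tmp_path):
        seq = "GCCCCGUUUAAAGGAAACCGU"
        a = tmp_path / "a.tsv"
        b = tmp_path / "b.tsv"
        header = "id\tsequence\torientation\tprecursor_id\tarm\n"
        a.write_text(header + f"x\t{seq}\t3to5\tp\t5p\n")
        b.write_text(header + f"x\t{seq[::-1]}\t5to3\tp\t5p\n")
        assert read_mirna_table(a) == read_mirna_table(b)

    def test_too_short_sequence_rejected(self, tmp_path):
        path = tmp_path / "m.tsv"
        path.write_text(
            "id\tsequence\torientation\tprecursor_id\tarm\nx\tAUGC\t5to3\tp\t5p\n"
        )
        with pytest.raises(ValueError, match="length"):
            read_mirna_table(path)

    def test_non_rna_character_named_in_error(self, tmp_path):
        path = tmp_path / "m.tsv"
        path.write_text(
            "id\tsequence\torientation\tprecursor_id\tarm\n"
            "x\tAUGCXAUGCAUGCAUGCAUGC\t5to3\tp\t5p\n"
        )
        with pytest.raises(ValueError, match="X"):
            read_mirna_table(path)

    def test_write_read_round_trip(self, tmp_path):
        mirnas = [MatureMiRNA("m1", "ACGUACGUACGUACGUACGUA", "p1", "5p")]
        path = tmp_path / "m.tsv"
        write_mirna_table(mirnas, path)
        assert read_mirna_table(path) == mirnas


class TestCountsTable:
    HEADER = "feature_id\tC\t1d\t2d\t3d\n"

    def test_two_by_four_table(self, tmp_path):
        path = tmp_path / "c.tsv"
        path.write_text(self.HEADER + "a\t1\t2\t3\t4\nb\t0\t0\t5\t6\n")
        df = read_counts_tsv(path)
        assert df.shape == (2, 4)
        assert list(df.columns) == ["C", "1d", "2d", "3d"]
        assert df.loc["b", "2d"] == 5

    def test_duplicate_feature_id_rejected(self, tmp_path):
        path = tmp_path / "c.tsv"
        path.write_text(self.HEADER + "a\t1\t2\t3\t4\na\t1\t2\t3\t4\n")
        with pytest.raises(ValueError, match="duplicate"):
            read_counts_tsv(path)

    def test_negative_count_rejected(self, tmp_path):
        path = tmp_path / "c.tsv"
        path.write_text(self.HEADER + "a\t1\t-3\t3\t4\n")
        with pytest.raises(ValueError, match="negative"):
            read_counts_tsv(path)

    def test_missing_cell_rejected(self, tmp_path):
        path = tmp_path / "c.tsv"
        path.write_text(self.HEADER + "a\t1\t\t3\t4\n")
        with pytest.raises(ValueError, match="missing"):
            read_counts_tsv(path)


class TestSequences:
    def test_fasta_round_trip_normalises_to_rna(self, tmp_path):
        path = tmp_path / "s.fasta"
        write_fasta({"t1": "ACGUACGU", "t2": "UUUUAAAA"}, path)
        assert read_fasta(path) == {"t1": "ACGUACGU", "t2": "UUUUAAAA"}

    def test_revcomp_rna(self):
        assert revcomp_rna("ACGU") == "ACGU"
        assert revcomp_rna("AACC") == "GGUU"

    def test_as_rna_maps_t_and_validates(self):
        assert as_rna("acgt") == "ACGU"
        with pytest.raises(ValueError, match="N"):
            as_rna("ACGN")

    def test_degradome_tag_validation(self):
        DegradomeTag("ACGTACGTACGTACGTACGT", "A", 3)
        with pytest.raises(ValueError, match="15"):
            DegradomeTag("ACGT", "A", 1)
        with pytest.raises(ValueError, match="negative"):
            DegradomeTag("ACGTACGTACGTACGTACGT", "A", -1)
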