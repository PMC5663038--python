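import numpy as np
import pandas as pd
import pytest

from epiconcord import core_io, synthdata
from epiconcord.core_io import (
    ContactMatrix,
    GeneModel,
    GenomicInterval,
    OrthologRecord,
    ParseError,
    ValidationError,
)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


class TestDomainTypes:
    def test_gene_model_rejects_bad_coords(self):
        with pytest.raises(ValidationError):
            GeneModel("g1", "chr1", 100, 100, "+")
        with pytest.raises(ValidationError):
            GeneModel("g1", "chr1", -1, 100, "+")
        with pytest.raises(ValidationError):
            GeneModel("g1", "chr1", 0, 100, "*")

    def test_interval_overlap(self):
        a = GenomicInterval("chr1", 0, 100)
        assert a.overlap(GenomicInterval("chr1", 50, 150)) == 50
        assert a.overlap(GenomicInterval("chr1", 100, 150)) == 0
        assert a.overlap(GenomicInterval("chr2", 0, 100)) == 0

    def test_ortholog_record_rejects_mark_for_absent_gene(self):
        with pytest.raises(ValidationError):
            OrthologRecord("p1", {"Ath": "g1"}, {("Aly", "H3K27me3"): True})

    def test_is_marked_tristate(self):
        rec = OrthologRecord(
            "p1", {"Ath": "g1", "Aly": "g2"}, {("Ath", "H3K27me3"): True}
        )
        assert rec.is_marked("Ath", "H3K27me3") is True
        assert rec.is_marked("Aly", "H3K27me3") is False  # present, unmarked
        assert rec.is_marked("Aal", "H3K27me3") is None  # absent -> NA


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------


def _write_gff(tmp_path, lines):
    path = tmp_path / "test.gff3"
    path.write_text("##gff-version 3\n" + "\n".join(lines) + "\n")
    return path


class TestGff3:
    def test_coordinate_convention_plus(self, tmp_path):
        path = _write_gff(
            tmp_path, ["chr1\tsrc\tgene\t1\t100\t.\t+\t.\tID=g1"]
        )
        (gene,) = core_io.read_gff3(path)
        assert (gene.start, gene.end, gene.strand) == (0, 100, "+")

    def test_coordinate_convention_minus(self, tmp_path):
        path = _write_gff(
            tmp_path, ["chr1\tsrc\tgene\t501\t1500\t.\t-\t.\tID=g1"]
        )
        (gene,) = core_io.read_gff3(path)
        assert (gene.start, gene.end, gene.strand) == (500, 1500, "-")

    def test_only_gene_features_kept(self, tmp_path):
        lines = [f"chr1\tsrc\tgene\t{i*1000+1}\t{i*1000+500}\t.\t+\t.\tID=g{i}" for i in range(3)]
        lines += [f"chr1\tsrc\tmRNA\t{i*1000+1}\t{i*1000+500}\t.\t+\t.\tID=m{i}" for i in range(7)]
        path = _write_gff(tmp_path, lines)
        assert len(core_io.read_gff3(path)) == 3

    def test_malformed_line_reports_line_number(self, tmp_path):
        path = _write_gff(tmp_path, ["chr1\tsrc\tgene\t1\t100"])
        with pytest.raises(ParseError, match=":2:"):
            core_io.read_gff3(path)

    def test_unknown_strand_skipped_with_warning(self, tmp_path):
        path = _write_gff(
            tmp_path,
            [
                "chr1\tsrc\tgene\t1\t100\t.\t.\t.\tID=g1",
                "chr1\tsrc\tgene\t200\t300\t.\t+\t.\tID=g2",
            ],
        )
        with pytest.warns(UserWarning, match="strand"):
            genes = core_io.read_gff3(path)
        assert [g.gene_id for g in genes] == ["g2"]

    def test_round_trip_bijection(self, tmp_path):
        genes = [
            GeneModel(f"g{i}", "chr1", i * 1000, i * 1000 + 500, "+-"[i % 2], "Ath")
            for i in range(10)
        ]
        path = tmp_path / "rt.gff3"
        core_io.write_gff3(genes, path)
        back = core_io.read_gff3(path, species="Ath")
        assert back == genes


# ---------------------------------------------------------------------------
# Marking tables
# ---------------------------------------------------------------------------


class TestMarkingTable:
    def test_round_trip(self, tmp_path):
        records = [
            OrthologRecord(
                "p1",
                {"Ath": "a1", "Aly": "l1", "Aal": "aa1"},
                {
                    ("Ath", "H3K27me3"): True,
                    ("Aly", "H3K27me3"): False,
                    ("Aal", "H3K27me3"): True,
                    ("Ath", "H3K4me3"): False,
                    ("Aly", "H3K4me3"): False,
                    ("Aal", "H3K4me3"): True,
                },
                True,
            ),
            OrthologRecord(
                "p2",
                {"Ath": "a2", "Aal": "aa2"},
                {
                    ("Ath", "H3K27me3"): False,
                    ("Aal", "H3K27me3"): False,
                    ("Ath", "H3K4me3"): True,
                    ("Aal", "H3K4me3"): False,
                },
                None,
                "missing_in_some",
            ),
        ]
        path = tmp_path / "marking.tsv"
        core_io.write_marking_table(records, path)
        back = core_io.read_marking_table(path)
        assert back == records

    def test_table1_fixture_round_trips_13515_records(self, tmp_path, table1_records):
        path = tmp_path / "table1.tsv"
        core_io.write_marking_table(table1_records, path)
        back = core_io.read_marking_table(path)
        assert len(back) == 13_515
        assert back == table1_records

    def test_flag_for_absent_gene_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text(
            "protogene_id\tgene_Ath\tgene_Aly\tgene_Aal\t"
            "H3K27me3_Ath\tH3K27me3_Aly\tH3K27me3_Aal\n"
            "p1\ta1\t.\taa1\t1\t1\t0\n"
        )
        with pytest.raises(ValidationError, match="absent"):
            core_io.read_marking_table(path, marks=["H3K27me3"])

    def test_missing_flag_for_present_gene_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text(
            "protogene_id\tgene_Ath\tgene_Aly\tgene_Aal\t"
            "H3K27me3_Ath\tH3K27me3_Aly\tH3K27me3_Aal\n"
            "p1\ta1\tl1\taa1\t1\t\t0\n"
        )
        with pytest.raises(ValidationError):
            core_io.read_marking_table(path, marks=["H3K27me3"])

    def test_na_flags_for_absent_gene_accepted(self, tmp_path):
        path = tmp_path / "ok.tsv"
        path.write_text(
            "protogene_id\tgene_Ath\tgene_Aly\tgene_Aal\t"
            "H3K27me3_Ath\tH3K27me3_Aly\tH3K27me3_Aal\n"
            "p1\ta1\tl1\t.\t1\t0\tNA\n"
        )
        (rec,) = core_io.read_marking_table(path, marks=["H3K27me3"])
        assert rec.is_marked("Aal", "H3K27me3") is None

    def test_duplicate_protogene_id_rejected(self, tmp_path):
        path = tmp_path / "dup.tsv"
        path.write_text(
            "protogene_id\tgene_Ath\tgene_Aly\tgene_Aal\t"
            "H3K27me3_Ath\tH3K27me3_Aly\tH3K27me3_Aal\n"
            "p1\ta1\tl1\taa1\t1\t0\t0\n"
            "p1\ta2\tl2\taa2\t0\t0\t0\n"
        )
        with pytest.raises(ValidationError, match="duplicate"):
            core_io.read_marking_table(path, marks=["H3K27me3"])


# ---------------------------------------------------------------------------
# Contact matrices
# ---------------------------------------------------------------------------


class TestContactMatrix:
    def test_symmetrization_by_max(self, tmp_path):
        path = tmp_path / "cm.tsv"
        path.write_text("0\t0\t1.5\n0\t0\t0\n0\t0\t0\n")
        cm = core_io.read_contact_matrix(path)
        assert cm.scores[2, 0] == 1.5
        assert cm.scores[0, 2] == 1.5

    def test_sentinel_stored_as_saturated(self, tmp_path):
        path = tmp_path / "cm.tsv"
        path.write_text("0\tW\n0.2\t0\n")
        cm = core_io.read_contact_matrix(path)
        assert cm.saturated[0, 1] and cm.saturated[1, 0]
        assert np.isnan(cm.scores[0, 1])

    def test_out_of_range_score_rejected(self, tmp_path):
        path = tmp_path / "cm.tsv"
        path.write_text("0\t2.5\n2.5\t0\n")
        with pytest.raises(ValidationError):
            core_io.read_contact_matrix(path)

    def test_negative_score_rejected(self, tmp_path):
        path = tmp_path / "cm.tsv"
        path.write_text("0\t-0.1\n-0.1\t0\n")
        with pytest.raises(ValidationError):
            core_io.read_contact_matrix(path)

    def test_non_square_rejected(self, tmp_path):
        path = tmp_path / "cm.tsv"
        path.write_text("0\t1\t1\n1\t0\t1\n")
        with pytest.raises(ParseError):
            core_io.read_contact_matrix(path)

    def test_round_trip(self, tmp_path):
        rng = np.random.default_rng(7)
        scores = np.clip(rng.uniform(0, 2, (5, 5)), 0, 2)
        scores = (scores + scores.T) / 2
        sat = np.zeros((5, 5), bool)
        sat[0, 4] = sat[4, 0] = True
        scores[sat] = np.nan
        cm = ContactMatrix("chr1", scores, sat)
        path = tmp_path / "cm.tsv"
        core_io.write_contact_matrix(cm, path)
        back = core_io.read_contact_matrix(path)
        assert np.array_equal(back.saturated, cm.saturated)
        np.testing.assert_array_equal(back.scores[~sat], cm.scores[~sat])


# ---------------------------------------------------------------------------
# Other formats
# ---------------------------------------------------------------------------


class TestOtherFormats:
    def test_bed_round_trip(self, tmp_path):
        ivs = [GenomicInterval("chr1", 0, 100), GenomicInterval("chr2", 50, 70)]
        path = tmp_path / "t.bed"
        core_io.write_bed(ivs, path)
        assert core_io.read_bed(path) == ivs

    def test_bedgraph_round_trip(self, tmp_path):
        df = pd.DataFrame(
            {"chrom": ["chr1", "chr1"], "start": [0, 100], "end": [100, 150],
             "score": [1.5, 0.25]}
        )
        path = tmp_path / "t.bedgraph"
        core_io.write_bedgraph(df, path)
        pd.testing.assert_frame_equal(core_io.read_bedgraph(path), df)

    def test_expression_round_trip(self, tmp_path):
        em = core_io.ExpressionMatrix(
            ["g1", "g2"], ["t1", "t2", "t3"], np.array([[1.0, 0.0, 2.5], [3, 4, 5]])
        )
        path = tmp_path / "expr.tsv"
        core_io.write_expression(em, path)
        back = core_io.read_expression(path)
        assert back.genes == em.genes and back.tissues == em.tissues
        np.testing.assert_array_equal(back.values, em.values)

    def test_expression_rejects_negative(self):
        with pytest.raises(ValidationError):
            core_io.ExpressionMatrix(["g1"], ["t1"], np.array([[-1.0]]))

    def test_fasta_round_trip(self, tmp_path):
        seqs = {"s1": "ACGTACGT" * 20, "s2": "TTTT"}
        path = tmp_path / "t.fa"
        core_io.write_fasta(seqs, path)
        assert core_io.read_fasta(path) == seqs

    def test_blocks_round_trip(self, tmp_path):
        df = pd.DataFrame({"block_id": ["b1", "b1", "b2"], "gene_id": ["g1", "g2", "g3"]})
        path = tmp_path / "blocks.tsv"
        core_io.write_blocks(df, path)
        pd.testing.assert_frame_equal(core_io.read_blocks(path), df)
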