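import io

import pytest

from hydroscan.genome_io import (GeneFeature, Genome, GenomeIOError,
                                 GenomeMetadata, ProteinRecord, read_fasta,
                                 read_features, read_metadata, read_newick,
                                 tree_leaf_names, write_fasta, write_features,
                                 write_metadata)


class TestFasta:
    def test_two_records_parse_in_order(self):
        recs = read_fasta(io.StringIO(">p1 desc\nMKV\n>p2\nACDE\n"), genome_id="g")
        assert [(r.protein_id, r.sequence) for r in recs] == [("p1", "MKV"),
                                                              ("p2", "ACDE")]
        assert all(r.genome_id == "g" for r in recs)

    def test_lowercase_uppercased_and_terminator_stripped(self):
        recs = read_fasta(io.StringIO(">p1\nmkv*\n"))
        assert recs[0].sequence == "MKV"

    @pytest.mark.parametrize("text,match", [
        ("", "empty"),
        ("MKV\n>p1\nACD\n", "malformed"),
        (">p1\nMKV\n>p1\nACD\n", "duplicate"),
        (">p1\nMKB\n", "alphabet"),  # B is ambiguous, rejected
    ])
    def test_malformed_inputs_raise(self, text, match):
        with pytest.raises(GenomeIOError, match=match):
            read_fasta(io.StringIO(text))

    def test_write_read_roundtrip(self, tmp_path):
        recs = [ProteinRecord("p1", "g", "MKV" * 50), ProteinRecord("p2", "g", "ACDEX")]
        path = tmp_path / "x.faa"
        write_fasta(recs, path)
        back = read_fasta(path, genome_id="g")
        assert back == recs


class TestFeatures:
    GFF = ("##gff-version 3\n"
           "chr\tsrc\tCDS\t11\t40\t.\t+\t0\tID=gene1;protein_id=p1\n"
           "chr\tsrc\tCDS\t100\t220\t.\t-\t0\tID=gene2;protein_id=p2\n")

    def test_gff3_converts_to_zero_based_half_open(self):
        feats = read_features(io.StringIO(self.GFF), dialect="gff3")
        assert (feats[0].start, feats[0].end, feats[0].strand) == (10, 40, "+")
        assert len(feats[0]) == 30  # == end - start internally, 40-11+1 printed

    def test_gff3_roundtrip_preserves_printed_coordinates(self, tmp_path):
        feats = read_features(io.StringIO(self.GFF), dialect="gff3")
        path = tmp_path / "x.gff3"
        write_features(feats, path, dialect="gff3")
        again = read_features(path, dialect="gff3")
        assert [(f.start, f.end, f.strand, f.gene_id, f.protein_id) for f in again] \
            == [(f.start, f.end, f.strand, f.gene_id, f.protein_id) for f in feats]
        text = path.read_text()
        assert "\t11\t40\t" in text and "\t100\t220\t" in text

    def test_tsv_roundtrip(self, tmp_path):
        feats = [GeneFeature("g1", "g", "chr", 10, 40, "+", "p1"),
                 GeneFeature("g2", "g", "chr", 99, 220, "-", None)]
        path = tmp_path / "x.tsv"
        write_features(feats, path, dialect="tsv")
        assert read_features(path, dialect="tsv", genome_id="g") == feats

    def test_undefined_strand_on_cds_rejected(self):
        bad = "chr\tsrc\tCDS\t1\t9\t.\t.\t0\tID=g1;protein_id=p1\n"
        with pytest.raises(GenomeIOError, match="strand"):
            read_features(io.StringIO(bad), dialect="gff3")

    def test_inverted_interval_rejected(self):
        bad = "chr\tsrc\tCDS\t40\t11\t.\t+\t0\tID=g1\n"
        with pytest.raises(GenomeIOError, match="end < start"):
            read_features(io.StringIO(bad), dialect="gff3")

    def test_order_stable(self):
        feats = read_features(io.StringIO(self.GFF), dialect="gff3")
        assert [f.gene_id for f in feats] == ["gene1", "gene2"]


class TestMetadata:
    def test_known_labels(self):
        md = read_metadata(io.StringIO(
            "genome_id\thabitat\tsubsection\ng1\tfreshwater\tIV\n"))
        assert md["g1"] == GenomeMetadata("g1", "freshwater", "IV")

    def test_unknown_habitat_maps_to_other_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            md = read_metadata(io.StringIO(
                "genome_id\thabitat\tsubsection\ng2\tswamp\tII\n"))
        assert md["g2"].habitat == "other"
        assert "swamp" in caplog.text

    def test_missing_subsection_is_unknown(self):
        md = read_metadata(io.StringIO("genome_id\thabitat\tsubsection\ng1\tcoastal\n"))
        assert md["g1"].subsection == "unknown"

    def test_duplicate_genome_rejected(self):
        text = ("genome_id\thabitat\tsubsection\n"
                "g1\tfreshwater\tI\ng1\tcoastal\tII\n")
        with pytest.raises(GenomeIOError, match="duplicate"):
            read_metadata(io.StringIO(text))

    def test_write_read_roundtrip(self, tmp_path):
        md = [GenomeMetadata("g1", "hot_spring", "V")]
        write_metadata(md, tmp_path / "m.tsv")
        assert read_metadata(tmp_path / "m.tsv")["g1"] == md[0]


class TestNewick:
    def test_leaves(self):
        tree = read_newick(io.StringIO("(a,(b,c));"))
        assert sorted(tree_leaf_names(tree)) == ["a", "b", "c"]

    def test_single_leaf(self):
        tree = read_newick(io.StringIO("a;"))
        assert tree_leaf_names(tree) == ["a"]

    def test_unbalanced_raises(self):
        with pytest.raises(GenomeIOError, match="parse"):
            read_newick(io.StringIO("(a,(b,c);"))


class TestGenomeInvariants:
    def test_duplicate_protein_ids_rejected(self):
        with pytest.raises(GenomeIOError, match="duplicate"):
            Genome("g", proteins=[ProteinRecord("p", "g", "MK"),
                                  ProteinRecord("p", "g", "AC")])

    def test_dangling_protein_link_rejected(self):
        with pytest.raises(GenomeIOError, match="unknown protein"):
            Genome("g", proteins=[ProteinRecord("p", "g", "MK")],
                   features=[GeneFeature("f", "g", "chr", 0, 9, "+", "zzz")])
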