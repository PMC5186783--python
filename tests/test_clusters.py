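import pytest

from hydroscan.clusters import (DEFAULT_HUP_LOOKUP,
                                classify_all, classify_hox, classify_hup,
                                classify_hyp, detect_xis_interruption,
                                find_clusters, partition_signature)
from hydroscan.families import ALL_FAMILIES, HYP_SYSTEM, FamilyPresence
from hydroscan.genome_io import GeneFeature, Genome, GenomeIOError, ProteinRecord

GENE_NT = 900
GAP_NT = 100


def layout(gid, order, strands=None, replicons=None):
    """Build a genome from an ordered gene list.

    ``order`` entries are family names, "bg" for background genes, or
    ("xis_in", family) to nest an xisC gene inside that family's span.
    """
    proteins, features = [], []
    presence = {}
    cursor = 0
    counts = {}
    for i, entry in enumerate(order):
        strand = strands[i] if strands else "+"
        replicon = replicons[i] if replicons else "chr"
        nested = None
        if isinstance(entry, tuple):
            _, family = entry
            nested = "xisC"
        else:
            family = entry
        counts[family] = counts.get(family, 0) + 1
        pid = f"{gid}_{family}_{counts[family]}"
        span = GENE_NT * (3 if nested else 1)
        features.append(GeneFeature(pid, gid, replicon, cursor, cursor + span,
                                    strand, pid))
        proteins.append(ProteinRecord(pid, gid, "MKVLAW" * 25))
        if nested:
            xid = f"{gid}_xisC_1"
            features.append(GeneFeature(xid, gid, replicon, cursor + GENE_NT,
                                        cursor + 2 * GENE_NT, "+", xid))
            proteins.append(ProteinRecord(xid, gid, "MKVLAW" * 25))
            counts["xisC"] = 1
        cursor += span + GAP_NT
    genome = Genome(gid, proteins=proteins, features=features)
    for fam in ALL_FAMILIES:
        n = counts.get(fam, 0)
        members = [f"{gid}_{fam}_{k + 1}" for k in range(n)]
        presence[fam] = FamilyPresence(gid, fam, "present" if n else "absent",
                                       n, members)
    return genome, presence


def mirrored(genome):
    total = max(f.end for f in genome.features) + 100
    feats = [GeneFeature(f.gene_id, f.genome_id, f.replicon_id,
                         total - f.end, total - f.start,
                         "-" if f.strand == "+" else "+", f.protein_id)
             for f in genome.features]
    return Genome(genome.genome_id, proteins=genome.proteins, features=feats)


class TestFindClusters:
    def test_adjacent_genes_form_one_cluster(self):
        genome, presence = layout("g", ["hoxE", "hoxF", "hoxU", "hoxY", "hoxH"])
        clusters = find_clusters(genome, presence, "hox")
        assert len(clusters) == 1
        assert clusters[0].families == ("hoxE", "hoxF", "hoxU", "hoxY", "hoxH")

    @pytest.mark.parametrize("n_between,expected", [(3, 1), (4, 2)])
    def test_max_intervening_boundary(self, n_between, expected):
        genome, presence = layout("g", ["hoxE"] + ["bg"] * n_between + ["hoxF"])
        clusters = find_clusters(genome, presence, "hox", max_intervening=3)
        assert len(clusters) == expected

    def test_different_replicons_never_cluster(self):
        genome, presence = layout("g", ["hupS", "hupL"],
                                  replicons=["chr", "plasmid"])
        assert len(find_clusters(genome, presence, "hup")) == 2

    def test_mirror_invariance(self):
        genome, presence = layout(
            "g", ["hoxE", "hoxF", "bg", "bg", "hoxU", "bg"] + ["bg"] * 5
            + ["hoxY", "hoxH", "bg", "hoxW"])
        a = find_clusters(genome, presence, "hox")
        b = find_clusters(mirrored(genome), presence, "hox")
        assert sorted(tuple(sorted(c.families)) for c in a) \
            == sorted(tuple(sorted(c.families)) for c in b)

    def test_input_order_invariance(self):
        genome, presence = layout("g", ["hypA", "hypB", "bg", "hypC"])
        shuffled = Genome(genome.genome_id, proteins=genome.proteins,
                          features=list(reversed(genome.features)))
        assert [c.families for c in find_clusters(genome, presence, "hyp")] \
            == [c.families for c in find_clusters(shuffled, presence, "hyp")]

    def test_member_without_coordinates_errors(self):
        genome, presence = layout("g", ["hoxE"])
        presence["hoxF"] = FamilyPresence("g", "hoxF", "present", 1, ["ghost"])
        genome.proteins.append(ProteinRecord("ghost", "g", "MKVLAW"))
        with pytest.raises(GenomeIOError, match="ghost"):
            find_clusters(genome, presence, "hox")

    def test_every_member_in_exactly_one_cluster(self):
        genome, presence = layout(
            "g", ["hypA", "bg", "hypB"] + ["bg"] * 5 + ["hypC", "hypD"]
            + ["bg"] * 5 + ["hypE"] + ["bg"] * 5 + ["hypF"])
        clusters = find_clusters(genome, presence, "hyp")
        members = [f for c in clusters for f in c.families]
        assert sorted(members) == sorted(HYP_SYSTEM)


SEP = ["bg"] * 5


class TestClassifyHox:
    def run(self, order, strands=None):
        genome, presence = layout("g", order, strands=strands)
        clusters = find_clusters(genome, presence, "hox")
        return classify_hox(clusters, presence)

    def test_group1(self):
        label = self.run(["hoxE", "hoxF", "hoxU", "hoxY", "hoxH"] + SEP + ["hoxW"])
        assert label.label == "G1"

    def test_group2(self):
        label = self.run(["hoxE", "hoxF", "hoxU", "hoxY", "hoxH", "hoxW"])
        assert label.label == "G2"

    def test_group3(self):
        label = self.run(["hoxE", "hoxF", "hoxU", "hoxY"] + SEP + ["hoxH"]
                         + SEP + ["hoxW"])
        assert label.label == "G3"

    def test_group7(self):
        label = self.run(["hoxF", "hoxU", "hoxY", "hoxH", "hoxW"] + SEP + ["hoxE"])
        assert label.label == "G7"

    def test_group4_via_lookup(self):
        label = self.run(["hoxE", "hoxF"] + SEP + ["hoxU", "hoxY", "hoxH", "hoxW"])
        assert label.label == "G4"
        assert label.partition_signature == "UYHW+EF"

    def test_unknown_signature_unclassified(self):
        label = self.run(["hoxE", "hoxF", "hoxU"] + SEP + ["hoxY", "hoxH", "hoxW"])
        assert label.label == "unclassified"

    def test_mixed_orientation_blocks_group1(self):
        order = ["hoxE", "hoxF", "hoxU", "hoxY", "hoxH"] + SEP + ["hoxW"]
        strands = ["+", "-", "+", "-", "+"] + ["+"] * 6
        label = self.run(order, strands=strands)
        assert label.label != "G1"

    def test_incomplete_set_is_an_error(self):
        genome, presence = layout("g", ["hoxE", "hoxF"])
        clusters = find_clusters(genome, presence, "hox")
        with pytest.raises(ValueError, match="complete"):
            classify_hox(clusters, presence)

    def test_mirror_invariant_labels(self):
        order = ["hoxE", "hoxF", "hoxU", "hoxY", "hoxH"] + SEP + ["hoxW"]
        genome, presence = layout("g", order)
        a = classify_hox(find_clusters(genome, presence, "hox"), presence)
        b = classify_hox(find_clusters(mirrored(genome), presence, "hox"), presence)
        assert a.label == b.label == "G1"
        assert a.partition_signature == b.partition_signature


class TestClassifyHup:
    def run(self, order):
        genome, presence = layout("g", order)
        clusters = find_clusters(genome, presence, "hup")
        return classify_hup(clusters, genome, presence)

    def test_clustered_no_interruption_is_g1(self):
        assert self.run(["hupS", "hupL", "hupW"]).label == "G1"

    def test_distal_w_is_g2(self):
        assert self.run(["hupS", "hupL"] + SEP + ["hupW"]).label == "G2"

    def test_xis_inside_hupl_changes_label(self):
        g1 = self.run(["hupS", "hupL", "hupW"])
        interrupted = self.run([("xis_in", "hupL"), "hupS", "hupW"])
        assert interrupted.interrupted_by == "hupL"
        assert interrupted.label != g1.label

    def test_axes_cover_five_groups(self):
        assert set(DEFAULT_HUP_LOOKUP.values()) == {"G1", "G2", "G3", "G4", "G5"}

    def test_split_subunits_unclassified(self):
        label = self.run(["hupS"] + SEP + ["hupL", "hupW"])
        assert label.label == "unclassified"

    def test_different_replicons_unclassified(self):
        genome, presence = layout("g", ["hupS", "hupL", "hupW"],
                                  replicons=["chr", "plasmid", "plasmid"])
        clusters = find_clusters(genome, presence, "hup")
        assert classify_hup(clusters, genome, presence).label == "unclassified"

    def test_split_feature_interruption_detected(self):
        # hupS annotated as two features flanking the xisC element
        gid = "g"
        feats = [
            GeneFeature("hupS_n", gid, "chr", 0, 400, "+", "g_hupS_1"),
            GeneFeature("xis", gid, "chr", 450, 1800, "+", "g_xisC_1"),
            GeneFeature("hupS_c", gid, "chr", 1850, 2300, "+", "g_hupS_1b"),
        ]
        prots = [ProteinRecord("g_hupS_1", gid, "MKVLAW" * 10),
                 ProteinRecord("g_xisC_1", gid, "MKVLAW" * 10),
                 ProteinRecord("g_hupS_1b", gid, "MKVLAW" * 10)]
        genome = Genome(gid, proteins=prots, features=feats)
        presence = {
            "hupS": FamilyPresence(gid, "hupS", "present", 1,
                                   ["g_hupS_1", "g_hupS_1b"]),
            "xisC": FamilyPresence(gid, "xisC", "present", 1, ["g_xisC_1"]),
        }
        assert detect_xis_interruption(genome, presence) == "hupS"


class TestClassifyHyp:
    def run(self, order):
        genome, presence = layout("g", order)
        clusters = find_clusters(genome, presence, "hyp")
        return classify_hyp(clusters, presence)

    def test_single_cluster_is_class_1(self):
        assert self.run(["hypA", "hypB", "hypC", "hypD", "hypE", "hypF"]).label == "1"

    def test_five_plus_one_is_class_2(self):
        label = self.run(["hypA", "hypB", "hypC", "hypD", "hypE"] + SEP + ["hypF"])
        assert label.label == "2"
        assert "F" in label.partition_signature.split("+")

    def test_fully_scattered(self):
        order = []
        for f in ("hypA", "hypB", "hypC", "hypD", "hypE", "hypF"):
            order += [f] + SEP
        label = self.run(order[:-5])
        assert label.label == "1+1+1+1+1+1"

    def test_signature_is_a_partition(self):
        label = self.run(["hypA", "hypB"] + SEP + ["hypC", "hypD", "hypE"]
                         + SEP + ["hypF"])
        letters = label.partition_signature.replace("+", "")
        assert sorted(letters) == ["A", "B", "C", "D", "E", "F"]
        assert label.label == "3+2+1"


class TestClassifyAll:
    def test_only_complete_systems_labelled(self):
        genome, presence = layout(
            "g", ["hoxE", "hoxF", "hoxU", "hoxY", "hoxH", "hoxW"] + SEP + ["hupS"])
        labels = classify_all(genome, presence)
        assert set(labels) == {"hox"}
        assert labels["hox"].label == "G2"
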