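import numpy as np
import pytest

from hydroscan.families import presence_map
from hydroscan.panel import build_panel, mutate_sequence
from hydroscan.pipeline import scan_genome
from hydroscan.synth import (DEFAULT_MIX, PlantError, PlantSpec, SiteMutation,
                             SystemPlan, Truncation, _apportion,
                             generate_cohort, generate_genome, hox_plan,
                             hup_plan, hyp_plan, write_genome)


class TestPanel:
    def test_panel_is_deterministic(self):
        a, b = build_panel(), build_panel()
        assert [q.sequence for f in a.families for q in f.query_sequences] \
            == [q.sequence for f in b.families for q in f.query_sequences]

    def test_mbh_anchor_carries_signature_residues(self, panel):
        seq = panel.query("mbh1_small").sequence
        assert all(seq[p - 1] == "C" for p in (17, 19, 20, 115, 120, 149))
        assert seq[241] == "P"

    def test_siblings_diverged_from_queries(self, panel):
        from hydroscan.align import local_score
        q = panel.query("hoxH")
        sib = panel.siblings["hoxH"]
        assert 0 < local_score(sib.sequence, q.sequence) \
            < local_score(q.sequence, q.sequence)


class TestMutate:
    def test_rate_respected_and_sites_avoided(self):
        rng = np.random.default_rng(0)
        seq = "A" * 200
        out = mutate_sequence(seq, 0.1, rng, avoid_positions=range(1, 51))
        diffs = [i for i, (a, b) in enumerate(zip(seq, out)) if a != b]
        assert len(diffs) == 20
        assert all(i >= 50 for i in diffs)


class TestGenerateGenome:
    def spec(self, **kwargs):
        base = dict(genome_id="t0", seed=11, decoys=12,
                    systems={"hox": hox_plan("G2"), "hyp": hyp_plan("1")})
        base.update(kwargs)
        return PlantSpec(**base)

    def test_same_seed_byte_identical_files(self, tmp_path, panel):
        for sub in ("a", "b"):
            genome, _ = generate_genome(self.spec(), panel)
            write_genome(genome, tmp_path / sub)
        for name in ("t0.faa", "t0.gff3"):
            assert (tmp_path / "a" / name).read_bytes() \
                == (tmp_path / "b" / name).read_bytes()

    def test_different_seed_different_genome(self, panel):
        a, _ = generate_genome(self.spec(), panel)
        b, _ = generate_genome(self.spec(seed=12), panel)
        assert [p.sequence for p in a.proteins] != [p.sequence for p in b.proteins]

    def test_unrealizable_layout_rejected_before_output(self, panel):
        spec = self.spec(decoys=2,
                         systems={"hyp": hyp_plan("1+1+1+1+1+1")})
        with pytest.raises(PlantError, match="isolate"):
            generate_genome(spec, panel)

    def test_foreign_gene_in_system_plan_rejected(self, panel):
        spec = self.spec(systems={"hox": SystemPlan(partition=[["hoxE", "hupS"]])})
        with pytest.raises(PlantError, match="foreign"):
            generate_genome(spec, panel)

    def test_truth_derives_from_spec(self, panel):
        spec = self.spec(mutations=[SiteMutation("hoxU", 28, "S")],
                         extra_copies={"hoxW": 1})
        _, truth = generate_genome(spec, panel)
        assert truth.family_copies["hoxW"] == 2
        assert "hoxU" in truth.degenerate_families
        assert truth.hox_functional is False
        assert truth.labels == {"hox": "G2", "hyp": "1"}

    def test_truncation_breaks_downstream_sites(self, panel):
        spec = self.spec(systems={"hup": hup_plan("G1"), "hyp": hyp_plan("1")},
                         mutations=[Truncation("hupS", 0.7)])
        _, truth = generate_genome(spec, panel)
        assert "hupS" in truth.degenerate_families

    def test_xis_interruption_nested_in_target_span(self, panel):
        spec = self.spec(systems={"hup": hup_plan("G3"), "hyp": hyp_plan("1")})
        genome, truth = generate_genome(spec, panel)
        feats = {f.gene_id: f for f in genome.features}
        hupS, xis = feats["t0_hupS"], feats["t0_xisC"]
        assert hupS.start < xis.start and xis.end < hupS.end
        assert truth.family_copies["xisC"] == 1

    def test_roundtrip_through_pipeline(self, panel):
        """The generator's core contract: the pipeline recovers the plant."""
        spec = self.spec(paralog_decoys=[("hoxH", 0.9)])
        genome, truth = generate_genome(spec, panel)
        scan = scan_genome(genome, panel)
        pm = presence_map(scan.presence)
        for family in pm:
            assert pm[family].status == truth.family_status(family), family
            assert pm[family].copy_number == truth.family_copies.get(family, 0)

    def test_background_never_confirms_at_default_thresholds(self, panel):
        # pure-background genome: the false-positive control
        spec = PlantSpec(genome_id="bg", seed=99, decoys=100, systems={})
        genome, _ = generate_genome(spec, panel)
        scan = scan_genome(genome, panel)
        assert all(not p.is_present for p in scan.presence)
        assert not any(h.rbh for h in scan.hits)


class TestCohort:
    def test_mix_counts_match_apportionment(self, panel):
        mix = {"hox_only": 0.3, "hup_only": 0.2, "both": 0.2, "none": 0.3}
        genomes, truth = generate_cohort(10, mix=mix, seed=5, panel=panel)
        assert len(genomes) == 10
        counts = _apportion(10, mix)
        assert counts == {"hox_only": 3, "hup_only": 2, "both": 2, "none": 3}
        hox_complete = (truth["hox_state"] == "complete").sum()
        assert hox_complete == counts["hox_only"] + counts["both"]
        free = ((truth["hox_state"] == "absent")
                & (truth["hup_state"] == "absent")).sum()
        assert free >= counts["none"]

    def test_single_genome_cohort(self, panel):
        genomes, truth = generate_cohort(1, mix={"both": 1.0}, seed=1, panel=panel)
        assert len(genomes) == 1 and len(truth) == 1

    def test_nonpositive_n_rejected(self, panel):
        with pytest.raises(ValueError):
            generate_cohort(0, seed=1, panel=panel)

    def test_bad_mix_rejected(self, panel):
        with pytest.raises(ValueError, match="sum to 1"):
            generate_cohort(4, mix={"both": 0.5}, seed=1, panel=panel)

    def test_seed_determinism_and_divergence(self, panel, tmp_path):
        mix = {"none": 1.0}
        _, t1 = generate_cohort(3, mix=mix, seed=7, panel=panel,
                                outdir=tmp_path / "c1")
        _, t2 = generate_cohort(3, mix=mix, seed=7, panel=panel,
                                outdir=tmp_path / "c2")
        g3, _ = generate_cohort(3, mix=mix, seed=8, panel=panel)
        assert t1.equals(t2)
        assert (tmp_path / "c1" / "syn000.faa").read_bytes() \
            == (tmp_path / "c2" / "syn000.faa").read_bytes()
        g1_seqs = (tmp_path / "c1" / "syn000.faa").read_text()
        assert g3[0].proteins[0].sequence not in g1_seqs
        assert (tmp_path / "c1" / "metadata.tsv").exists()
        assert (tmp_path / "c1" / "truth.tsv").exists()
        assert (tmp_path / "c1" / "manifest.yaml").exists()

    def test_default_mix_sums_to_one(self):
        assert sum(DEFAULT_MIX.values()) == pytest.approx(1.0)
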