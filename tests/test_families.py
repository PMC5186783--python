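import pytest

from hydroscan.families import (ALL_FAMILIES, HOX_SYSTEM, HUP_SYSTEM,
                                HYP_SYSTEM, NIF_REQUIRED, NIF_SYSTEM,
                                FamilyPresence, apply_motif_downgrades,
                                call_capability, call_nitrogen_fixing,
                                call_presence, complete_hox, complete_hup,
                                complete_hyp, presence_frame, presence_map,
                                system_state)
from hydroscan.genome_io import Genome, ProteinRecord
from hydroscan.homology import HomologHit
from hydroscan.motifs import MotifReport, SiteOutcome


def make_presence(gid="g", present=(), degenerate=()):
    out = {}
    for f in ALL_FAMILIES:
        if f in degenerate:
            out[f] = FamilyPresence(gid, f, "present_degenerate", 1, [f"{gid}_{f}"])
        elif f in present:
            out[f] = FamilyPresence(gid, f, "present", 1, [f"{gid}_{f}"])
        else:
            out[f] = FamilyPresence(gid, f, "absent", 0, [])
    return out


def report(family, protein, conserved=True):
    return MotifReport(
        motif_id=f"{family}_motif", target_protein_id=protein,
        outcomes=[SiteOutcome(1, 1, "C", conserved)])


def reports_for(pmap, systems=("hoxE", "hoxF", "hoxU", "hoxY", "hoxH",
                               "hupS", "hupL"), bad=()):
    out = {}
    for f in systems:
        if pmap[f].is_present:
            out[f] = [report(f, pid, conserved=f not in bad)
                      for pid in pmap[f].member_protein_ids]
    return out


class TestCallPresence:
    def hit(self, fam, pid, rbh=True):
        return HomologHit(fam, "g", pid, f"Q_{fam}", 500.0, 1e-50, -50.0, rbh)

    def genome(self, n=4):
        return Genome("g", proteins=[ProteinRecord(f"p{i}", "g", "MKVLAW" * 20)
                                     for i in range(n)])

    def test_two_confirmed_hoxw_hits_give_copy_number_two(self):
        hits = [self.hit("hoxW", "p0"), self.hit("hoxW", "p1")]
        pmap = presence_map(call_presence(hits, self.genome()))
        assert pmap["hoxW"].status == "present"
        assert pmap["hoxW"].copy_number == 2
        assert pmap["hoxW"].member_protein_ids == ["p0", "p1"]

    def test_no_hits_means_every_family_absent(self):
        presence = call_presence([], self.genome())
        assert all(p.status == "absent" for p in presence)
        assert {p.family_name for p in presence} == set(ALL_FAMILIES)

    def test_nonreciprocal_hits_do_not_count(self, caplog):
        hits = [self.hit("hypA", "p0", rbh=True), self.hit("hypA", "p1", rbh=False)]
        with caplog.at_level("INFO"):
            pmap = presence_map(call_presence(hits, self.genome()))
        assert pmap["hypA"].copy_number == 1
        hits = [self.hit("hypB", "p0", rbh=False)]
        pmap = presence_map(call_presence(hits, self.genome()))
        assert pmap["hypB"].status == "absent"

    def test_foreign_genome_hit_rejected(self):
        bad = HomologHit("hoxH", "other", "p0", "Q_hoxH", 500.0, 1e-50, -50.0, True)
        with pytest.raises(ValueError, match="other"):
            call_presence([bad], self.genome())


class TestCompletenessRules:
    def test_complete_hox_needs_all_six(self):
        assert complete_hox(make_presence(present=HOX_SYSTEM))
        assert not complete_hox(make_presence(present=["hoxW"]))  # W without EFUYH
        assert not complete_hox(make_presence(present=HOX_SYSTEM[:-1]))

    def test_degenerate_member_breaks_completeness(self):
        pmap = make_presence(present=[f for f in HOX_SYSTEM if f != "hoxU"],
                             degenerate=["hoxU"])
        assert not complete_hox(pmap)

    def test_complete_hup_and_hyp(self):
        assert complete_hup(make_presence(present=HUP_SYSTEM))
        assert not complete_hup(make_presence(present=["hupS", "hupL"]))
        assert complete_hyp(make_presence(present=HYP_SYSTEM))
        assert not complete_hyp(make_presence(present=HYP_SYSTEM[:4]))

    def test_nif_rule_ignores_dispensable_genes(self):
        assert call_nitrogen_fixing(make_presence(present=NIF_REQUIRED))
        assert call_nitrogen_fixing(make_presence(present=NIF_SYSTEM))
        assert not call_nitrogen_fixing(
            make_presence(present=[f for f in NIF_REQUIRED if f != "nifH"]))


class TestSystemState:
    def test_three_states(self):
        assert system_state(make_presence(present=HOX_SYSTEM), "hox") == "complete"
        assert system_state(make_presence(present=["hoxE"]), "hox") == "incomplete"
        assert system_state(make_presence(), "hox") == "absent"

    def test_degenerate_counts_as_gene_present(self):
        pmap = make_presence(degenerate=["hoxE"])
        assert system_state(pmap, "hox") == "incomplete"


class TestCapability:
    def test_all_criteria_met(self):
        pmap = make_presence(present=HOX_SYSTEM + HYP_SYSTEM)
        call = call_capability(pmap.values(), reports_for(pmap), genome_id="g")
        assert call.hox_functional and not call.hup_functional
        assert ("3d", "candidate", []) in call.o2_tolerant_candidates

    def test_incomplete_hyp_blocks_and_is_named(self):
        pmap = make_presence(present=HOX_SYSTEM + ("hypA", "hypB"))
        call = call_capability(pmap.values(), reports_for(pmap), genome_id="g")
        assert not call.hox_functional
        assert any("hyp" in r for r in call.reasons)

    def test_degenerate_motif_blocks(self):
        pmap = make_presence(present=HOX_SYSTEM + HYP_SYSTEM)
        call = call_capability(pmap.values(), reports_for(pmap, bad=("hoxU",)),
                               genome_id="g")
        assert not call.hox_functional
        assert any("hoxU" in r for r in call.reasons)

    def test_missing_motif_report_is_an_error(self):
        pmap = make_presence(present=HOX_SYSTEM + HYP_SYSTEM)
        with pytest.raises(ValueError, match="missing motif report"):
            call_capability(pmap.values(), {}, genome_id="g")

    def test_every_false_verdict_carries_reasons(self):
        pmap = make_presence(present=["hoxE", "hupS"])
        call = call_capability(pmap.values(), reports_for(pmap), genome_id="g")
        assert not call.hox_functional and not call.hup_functional \
            and not call.nitrogen_fixing
        assert len(call.reasons) >= 3

    def test_deterministic(self):
        pmap = make_presence(present=["hoxE", "hoxW", "hupS"])
        a = call_capability(pmap.values(), reports_for(pmap), genome_id="g")
        b = call_capability(pmap.values(), reports_for(pmap), genome_id="g")
        assert a == b

    def test_monotone_under_family_removal(self):
        base = HOX_SYSTEM + HUP_SYSTEM + HYP_SYSTEM + NIF_REQUIRED
        pmap = make_presence(present=base)
        full = call_capability(pmap.values(), reports_for(pmap), genome_id="g")
        assert full.hox_functional and full.hup_functional and full.nitrogen_fixing
        for removed in base:
            sub = make_presence(present=[f for f in base if f != removed])
            call = call_capability(sub.values(), reports_for(sub), genome_id="g")
            assert call.hox_functional <= full.hox_functional
            assert call.hup_functional <= full.hup_functional
            assert call.nitrogen_fixing <= full.nitrogen_fixing


class TestO2Tolerance:
    def mbh_reports(self, pmap, conserved=True):
        reports = reports_for(pmap)
        reports["mbh1_small"] = [report("mbh1_small", "g_mbh1_small", conserved)]
        return reports

    def test_full_accessory_set_is_candidate(self):
        pmap = make_presence(present=("mbh1_large", "mbh1_small", "hoxZ", "hoxM",
                                      "hoxL", "hoxO", "hoxQ", "hoxR", "hoxT",
                                      "hoxV") + HYP_SYSTEM)
        call = call_capability(pmap.values(), self.mbh_reports(pmap), genome_id="g")
        assert ("1", "candidate") in [(g, v) for g, v, _ in call.o2_tolerant_candidates]

    def test_minimal_accessories_only_is_questionable(self):
        pmap = make_presence(present=("mbh1_large", "mbh1_small", "hoxZ", "hoxM")
                             + HYP_SYSTEM)
        call = call_capability(pmap.values(), self.mbh_reports(pmap), genome_id="g")
        entry = next(e for e in call.o2_tolerant_candidates if e[0] == "1")
        assert entry[1] == "questionable"
        assert any("hoxL" in r for r in entry[2])

    def test_broken_signature_rejects(self):
        pmap = make_presence(present=("mbh1_large", "mbh1_small", "hoxZ", "hoxM"))
        call = call_capability(pmap.values(), self.mbh_reports(pmap, conserved=False),
                               genome_id="g")
        entry = next(e for e in call.o2_tolerant_candidates if e[0] == "1")
        assert entry[1] == "rejected"

    def test_3b_requires_all_subunits_and_hyp(self):
        present = ("sh3b_alpha", "sh3b_beta", "sh3b_gamma", "sh3b_delta") + HYP_SYSTEM
        pmap = make_presence(present=present)
        reports = reports_for(pmap)
        reports["sh3b_delta"] = [report("sh3b_delta", "g_sh3b_delta", True)]
        call = call_capability(pmap.values(), reports, genome_id="g")
        assert ("3b", "candidate") in [(g, v) for g, v, _ in call.o2_tolerant_candidates]
        # only hypAB, like a strain unable to mature the enzyme
        pmap2 = make_presence(present=("sh3b_alpha", "sh3b_beta", "sh3b_gamma",
                                       "sh3b_delta", "hypA", "hypB"))
        reports2 = {"sh3b_delta": [report("sh3b_delta", "g_sh3b_delta", True)]}
        call2 = call_capability(pmap2.values(), reports2, genome_id="g")
        entry = next(e for e in call2.o2_tolerant_candidates if e[0] == "3b")
        assert entry[1] == "rejected"
        assert any("hyp" in r for r in entry[2])


class TestDowngrades:
    def test_all_copies_degenerate_downgrades(self):
        presence = [FamilyPresence("g", "hoxU", "present", 1, ["p1"])]
        out = apply_motif_downgrades(presence, {"hoxU": [report("hoxU", "p1", False)]})
        assert out[0].status == "present_degenerate"

    def test_one_intact_copy_keeps_family_functional(self):
        presence = [FamilyPresence("g", "hoxU", "present", 2, ["p1", "p2"])]
        reports = {"hoxU": [report("hoxU", "p1", False), report("hoxU", "p2", True)]}
        out = apply_motif_downgrades(presence, reports)
        assert out[0].status == "present"


class TestMatrix:
    def test_presence_frame_codes(self):
        by_genome = {"g1": list(make_presence("g1", present=["hoxE"],
                                              degenerate=["hupS"]).values())}
        df = presence_frame(by_genome)
        assert df.loc["g1", "hoxE"] == "P"
        assert df.loc["g1", "hupS"] == "D"
        assert df.loc["g1", "hoxH"] == "A"
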