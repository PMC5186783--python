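"""Family presence calls, gene-set completeness rules, capability verdicts.

A strain is called able to produce a functional hydrogenase on three
minimal criteria: (1) the complete structural gene set including the
system-specific endopeptidase, (2) the complete hypABCDEF maturation set,
and (3) conserved catalytic residues in every structural subunit.
Nitrogen fixation requires nifH + nifDK + nifBEN; nifUSV are dispensable
and ignored. O2-tolerant candidates (groups 1, 3b, 3d) are graded
separately, with the membrane-bound (MBH, group 1) verdict additionally
conditioned on the hox accessory maturation genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .genome_io import Genome
from .homology import HomologHit
from .motifs import MotifReport

logger = logging.getLogger(__name__)

HOX_STRUCTURAL = ("hoxE", "hoxF", "hoxU", "hoxY", "hoxH")
HOX_SYSTEM = HOX_STRUCTURAL + ("hoxW",)
HUP_SYSTEM = ("hupS", "hupL", "hupW")
HYP_SYSTEM = ("hypA", "hypB", "hypC", "hypD", "hypE", "hypF")
NIF_REQUIRED = ("nifH", "nifD", "nifK", "nifB", "nifE", "nifN")
NIF_DISPENSABLE = ("nifU", "nifS", "nifV")
NIF_SYSTEM = NIF_REQUIRED + NIF_DISPENSABLE
MBH_STRUCTURAL = ("mbh1_large", "mbh1_small")
MBH_ACCESSORY_MINIMUM = ("hoxZ", "hoxM")
MBH_ACCESSORY_FULL = ("hoxZ", "hoxM", "hoxL", "hoxO", "hoxQ", "hoxR", "hoxT", "hoxV")
SH3B_SUBUNITS = ("sh3b_alpha", "sh3b_beta", "sh3b_gamma", "sh3b_delta")
XIS_FAMILY = "xisC"

ALL_FAMILIES = (HOX_SYSTEM + HUP_SYSTEM + HYP_SYSTEM + NIF_SYSTEM
                + MBH_STRUCTURAL + MBH_ACCESSORY_FULL
                + SH3B_SUBUNITS + (XIS_FAMILY,))

SYSTEM_FAMILIES = {"hox": HOX_SYSTEM, "hup": HUP_SYSTEM, "hyp": HYP_SYSTEM,
                   "nif": NIF_SYSTEM}

# structural subunits whose presence demands a motif report before a
# capability verdict can be issued
MOTIF_CHECKED = {
    "hox": HOX_STRUCTURAL,
    "hup": ("hupS", "hupL"),
}


@dataclass
class FamilyPresence:
    genome_id: str
    family_name: str
    status: str  # present | present_degenerate | absent
    copy_number: int = 0
    member_protein_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.status not in ("present", "present_degenerate", "absent"):
            raise ValueError(f"invalid status {self.status!r}")
        if (self.status == "absent") != (self.copy_number == 0):
            raise ValueError("status 'absent' iff copy_number == 0")

    @property
    def is_present(self) -> bool:
        """Gene physically present (conserved or degenerate)."""
        return self.status != "absent"


@dataclass
class CapabilityCall:
    genome_id: str
    hox_functional: bool
    hup_functional: bool
    nitrogen_fixing: bool
    o2_tolerant_candidates: list[tuple[str, str, list[str]]] = field(default_factory=list)
    reasons: list[str] = field(default_factory=list)


PresenceMap = Mapping[str, FamilyPresence]


def call_presence(hits: Sequence[HomologHit], genome: Genome,
                  families: Sequence[str] = ALL_FAMILIES) -> list[FamilyPresence]:
    """Fold homolog hits into per-family presence states for one genome.

    A family is present iff it has at least one RBH-confirmed hit;
    copy number counts distinct confirmed hit proteins. Families whose
    only hits fail the reciprocal check are called absent with a note.
    """
    for hit in hits:
        if hit.genome_id != genome.genome_id:
            raise ValueError(
                f"hit for genome {hit.genome_id!r} passed with genome "
                f"{genome.genome_id!r}")
    by_family: dict[str, list[HomologHit]] = {f: [] for f in families}
    for hit in hits:
        by_family.setdefault(hit.family_name, []).append(hit)
    out: list[FamilyPresence] = []
    for family in families:
        confirmed = sorted({h.protein_id for h in by_family[family] if h.rbh})
        if confirmed:
            out.append(FamilyPresence(genome.genome_id, family, "present",
                                      len(confirmed), confirmed))
        else:
            if by_family[family]:
                logger.info("genome %s: %d non-reciprocal hit(s) for %s; called absent",
                            genome.genome_id, len(by_family[family]), family)
            out.append(FamilyPresence(genome.genome_id, family, "absent", 0, []))
    return out


def presence_map(presence: Iterable[FamilyPresence]) -> dict[str, FamilyPresence]:
    return {p.family_name: p for p in presence}


def _all_present(presence: PresenceMap, families: Sequence[str]) -> bool:
    return all(
        f in presence and presence[f].status == "present" for f in families
    )


def complete_hox(presence: PresenceMap) -> bool:
    """All six hox genes (EFUYH + the hoxW endopeptidase) strictly present."""
    return _all_present(presence, HOX_SYSTEM)


def complete_hup(presence: PresenceMap) -> bool:
    """hupS + hupL + the hupW peptidase strictly present."""
    return _all_present(presence, HUP_SYSTEM)


def complete_hyp(presence: PresenceMap) -> bool:
    """All six hypABCDEF maturation genes strictly present."""
    return _all_present(presence, HYP_SYSTEM)


def call_nitrogen_fixing(presence: PresenceMap) -> bool:
    """nifH + nifDK + nifBEN present; dispensable nifUSV ignored."""
    return _all_present(presence, NIF_REQUIRED)


def system_state(presence: PresenceMap, system: str) -> str:
    """Three-state gene-content summary: complete / incomplete / absent.

    ``absent`` means no member of the system is physically present
    (degenerate copies count as present genes); ``complete`` applies the
    system's completeness rule; anything in between is ``incomplete``.
    """
    families = SYSTEM_FAMILIES[system]
    n_members = sum(1 for f in families if f in presence and presence[f].is_present)
    if n_members == 0:
        return "absent"
    if system == "nif":
        return "complete" if call_nitrogen_fixing(presence) else "incomplete"
    rule = {"hox": complete_hox, "hup": complete_hup, "hyp": complete_hyp}[system]
    return "complete" if rule(presence) else "incomplete"


def apply_motif_downgrades(presence: Iterable[FamilyPresence],
                           reports: Mapping[str, Sequence[MotifReport]]
                           ) -> list[FamilyPresence]:
    """Downgrade present families to present_degenerate on degenerate motifs.

    ``reports`` maps family name to the motif reports of its member
    proteins. A family is downgraded when none of its members has fully
    conserved motifs — a single intact copy keeps the family functional.
    """
    out: list[FamilyPresence] = []
    for p in presence:
        fam_reports = reports.get(p.family_name, [])
        if p.status == "present" and fam_reports:
            per_member: dict[str, list[str]] = {}
            for r in fam_reports:
                per_member.setdefault(r.target_protein_id, []).append(r.verdict)
            members_with_reports = [m for m in p.member_protein_ids if m in per_member]
            if members_with_reports and all(
                    "degenerate" in per_member[m] for m in members_with_reports):
                p = FamilyPresence(p.genome_id, p.family_name, "present_degenerate",
                                   p.copy_number, list(p.member_protein_ids))
        out.append(p)
    return out


def _motif_verdicts(presence: PresenceMap, reports: Mapping[str, Sequence[MotifReport]],
                    system: str) -> tuple[bool, list[str]]:
    """(all structural motifs conserved, reasons for every failure)."""
    reasons: list[str] = []
    ok = True
    for family in MOTIF_CHECKED[system]:
        p = presence.get(family)
        if p is None or not p.is_present:
            continue
        fam_reports = reports.get(family, [])
        if not fam_reports:
            raise ValueError(
                f"missing motif report for present structural subunit {family!r} "
                f"in genome {p.genome_id!r}")
        per_member: dict[str, bool] = {}
        for r in fam_reports:
            per_member[r.target_protein_id] = (
                per_member.get(r.target_protein_id, True) and r.verdict == "conserved")
        if not any(per_member.values()):
            ok = False
            reasons.append(f"{family}: catalytic residues degenerate in all copies")
    return ok, reasons


def call_capability(presence: Iterable[FamilyPresence],
                    motif_reports: Mapping[str, Sequence[MotifReport]],
                    genome_id: Optional[str] = None) -> CapabilityCall:
    """Apply the three minimal functionality criteria plus nif and the
    O2-tolerance grading.

    hox_functional requires the complete hox set, the complete hyp set and
    conserved catalytic residues in every hox structural subunit;
    hup_functional likewise for hupSLW. Every false verdict carries a
    reason naming the failed criterion. Deterministic: same inputs yield
    identical output including reason order.
    """
    pmap = presence_map(presence)
    if genome_id is None:
        genome_id = next(iter(pmap.values())).genome_id if pmap else ""
    reasons: list[str] = []

    hyp_ok = complete_hyp(pmap)

    hox_sets = complete_hox(pmap)
    hox_motifs_ok, hox_motif_reasons = _motif_verdicts(pmap, motif_reports, "hox")
    hox_functional = hox_sets and hyp_ok and hox_motifs_ok
    if not hox_functional:
        if not hox_sets:
            missing = [f for f in HOX_SYSTEM
                       if f not in pmap or pmap[f].status != "present"]
            reasons.append(f"hox: structural set incomplete ({', '.join(missing)})")
        if not hyp_ok:
            missing = [f for f in HYP_SYSTEM
                       if f not in pmap or pmap[f].status != "present"]
            reasons.append(f"hox: hyp maturation set incomplete ({', '.join(missing)})")
        reasons.extend(f"hox: {r}" for r in hox_motif_reasons)

    hup_sets = complete_hup(pmap)
    hup_motifs_ok, hup_motif_reasons = _motif_verdicts(pmap, motif_reports, "hup")
    hup_functional = hup_sets and hyp_ok and hup_motifs_ok
    if not hup_functional:
        if not hup_sets:
            missing = [f for f in HUP_SYSTEM
                       if f not in pmap or pmap[f].status != "present"]
            reasons.append(f"hup: structural set incomplete ({', '.join(missing)})")
        if not hyp_ok:
            missing = [f for f in HYP_SYSTEM
                       if f not in pmap or pmap[f].status != "present"]
            reasons.append(f"hup: hyp maturation set incomplete ({', '.join(missing)})")
        reasons.extend(f"hup: {r}" for r in hup_motif_reasons)

    nitrogen_fixing = call_nitrogen_fixing(pmap)
    if not nitrogen_fixing:
        missing = [f for f in NIF_REQUIRED
                   if f not in pmap or pmap[f].status != "present"]
        reasons.append(f"nif: required genes missing ({', '.join(missing)})")

    o2 = _o2_tolerant_candidates(pmap, motif_reports, hox_functional)
    return CapabilityCall(genome_id=genome_id, hox_functional=hox_functional,
                          hup_functional=hup_functional,
                          nitrogen_fixing=nitrogen_fixing,
                          o2_tolerant_candidates=o2, reasons=reasons)


def _o2_tolerant_candidates(pmap: PresenceMap,
                            motif_reports: Mapping[str, Sequence[MotifReport]],
                            hox_functional: bool) -> list[tuple[str, str, list[str]]]:
    out: list[tuple[str, str, list[str]]] = []

    # group 1 (membrane-bound, MBH): structural pair + proximal-cluster
    # signature + at minimum the hoxZ/hoxM accessories; the full
    # hoxZMLOQRTV set elevates the verdict from questionable to candidate
    if any(f in pmap and pmap[f].is_present for f in MBH_STRUCTURAL):
        reasons: list[str] = []
        pair_ok = _all_present(pmap, MBH_STRUCTURAL)
        if not pair_ok:
            missing = [f for f in MBH_STRUCTURAL
                       if f not in pmap or pmap[f].status != "present"]
            reasons.append(f"structural pair incomplete ({', '.join(missing)})")
        sig_reports = motif_reports.get("mbh1_small", [])
        sig_ok = bool(sig_reports) and any(r.verdict == "conserved" for r in sig_reports)
        if pair_ok and not sig_ok:
            reasons.append("proximal [4Fe3S] six-Cys + Pro signature not conserved")
        minimum_ok = _all_present(pmap, MBH_ACCESSORY_MINIMUM)
        full_ok = _all_present(pmap, MBH_ACCESSORY_FULL)
        if not minimum_ok:
            missing = [f for f in MBH_ACCESSORY_MINIMUM
                       if f not in pmap or pmap[f].status != "present"]
            reasons.append(f"accessory minimum missing ({', '.join(missing)})")
        if pair_ok and sig_ok and minimum_ok and full_ok:
            out.append(("1", "candidate", reasons))
        elif pair_ok and sig_ok and minimum_ok:
            missing = [f for f in MBH_ACCESSORY_FULL
                       if f not in pmap or pmap[f].status != "present"]
            reasons.append(f"accessory set incomplete ({', '.join(missing)})")
            out.append(("1", "questionable", reasons))
        else:
            out.append(("1", "rejected", reasons))

    # group 3b (tetrameric bifunctional): all four subunits + complete hyp
    # + the small-subunit [4Fe4S] four-Cys ligand set
    if any(f in pmap and pmap[f].is_present for f in SH3B_SUBUNITS):
        reasons = []
        subunits_ok = _all_present(pmap, SH3B_SUBUNITS)
        if not subunits_ok:
            missing = [f for f in SH3B_SUBUNITS
                       if f not in pmap or pmap[f].status != "present"]
            reasons.append(f"subunits incomplete ({', '.join(missing)})")
        hyp_ok = complete_hyp(pmap)
        if not hyp_ok:
            missing = [f for f in HYP_SYSTEM
                       if f not in pmap or pmap[f].status != "present"]
            reasons.append(f"hyp maturation set incomplete ({', '.join(missing)})")
        sig_reports = motif_reports.get("sh3b_delta", [])
        sig_ok = bool(sig_reports) and any(r.verdict == "conserved" for r in sig_reports)
        if subunits_ok and not sig_ok:
            reasons.append("small-subunit [4Fe4S] cysteine ligands not conserved")
        verdict = "candidate" if (subunits_ok and hyp_ok and sig_ok) else "rejected"
        out.append(("3b", verdict, reasons))

    # group 3d (soluble bidirectional): the hox criteria themselves
    if any(f in pmap and pmap[f].is_present for f in HOX_SYSTEM):
        if hox_functional:
            out.append(("3d", "candidate", []))
        # a non-functional hox system is simply not a 3d candidate; the
        # hox reasons already explain why

    return out


# ---------------------------------------------------------------------------
# Matrix / table I/O

STATUS_CODE = {"present": "P", "present_degenerate": "D", "absent": "A"}
CODE_STATUS = {v: k for k, v in STATUS_CODE.items()}


def presence_frame(presence_by_genome: Mapping[str, Sequence[FamilyPresence]],
                   families: Sequence[str] = ALL_FAMILIES) -> pd.DataFrame:
    """Presence matrix: rows = genomes, columns = families, cells P/D/A."""
    rows = {}
    for gid in sorted(presence_by_genome):
        pmap = presence_map(presence_by_genome[gid])
        rows[gid] = {f: STATUS_CODE[pmap[f].status] if f in pmap else "A"
                     for f in families}
    df = pd.DataFrame.from_dict(rows, orient="index", columns=list(families))
    df.index.name = "genome_id"
    return df


def read_presence_frame(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="genome_id")


def presence_from_frame(df: pd.DataFrame) -> dict[str, dict[str, FamilyPresence]]:
    """Rebuild presence maps from a matrix (copy numbers collapse to 0/1)."""
    out: dict[str, dict[str, FamilyPresence]] = {}
    for gid, row in df.iterrows():
        pmap = {}
        for family, code in row.items():
            status = CODE_STATUS[code]
            pmap[family] = FamilyPresence(
                gid, family, status, 0 if status == "absent" else 1,
                [] if status == "absent" else ["?"])
        out[gid] = pmap
    return out


def capability_frame(calls: Sequence[CapabilityCall]) -> pd.DataFrame:
    rows = []
    for c in sorted(calls, key=lambda c: c.genome_id):
        rows.append({
            "genome_id": c.genome_id,
            "hox_functional": c.hox_functional,
            "hup_functional": c.hup_functional,
            "nitrogen_fixing": c.nitrogen_fixing,
            "o2_tolerant": ";".join(f"{g}:{v}" for g, v, _ in c.o2_tolerant_candidates),
            "reasons": ";".join(c.reasons),
        })
    return pd.DataFrame(rows).set_index("genome_id") if rows else pd.DataFrame()
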