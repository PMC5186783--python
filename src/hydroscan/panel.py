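"""Built-in synthetic query panel, reference proteome and motif anchors.

Real survey runs would load a curated panel of reference hydrogenase,
maturation and nitrogenase proteins; this module fabricates a synthetic
stand-in with the statistical structure such a panel has: one query per
family at a realistic length, shared-ancestry similarity groups for the
[NiFe] large and small subunits (so cross-family hits and reciprocal-best
rejection are exercised), paralog siblings living in the query source
proteome, and catalytic-residue anchors at defined positions (the
membrane-bound-hydrogenase proximal-cluster signature keeps the published
Hyd-1 numbering: Cys 17/19/20/115/120/149 and Pro 242).

The construction is deterministic (fixed internal seed) so panels are
byte-identical across runs and machines.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import yaml

from .families import ALL_FAMILIES
from .genome_io import ProteinRecord, write_fasta
from .homology import QueryFamily, default_threshold
from .motifs import MotifDefinition, MotifSite

PANEL_SEED = 710823  # fixed: the panel is reference data, not a simulation

AA20 = "ACDEFGHIKLMNPQRSTVWY"

# nominal query lengths (aa), in the range of the real proteins
FAMILY_LENGTHS = {
    "hoxE": 170, "hoxF": 530, "hoxU": 240, "hoxY": 185, "hoxH": 470,
    "hoxW": 160,
    "hupS": 320, "hupL": 530, "hupW": 140,
    "hypA": 110, "hypB": 270, "hypC": 90, "hypD": 370, "hypE": 340, "hypF": 600,
    "nifH": 295, "nifD": 480, "nifK": 520, "nifB": 490, "nifE": 470,
    "nifN": 460, "nifU": 300, "nifS": 400, "nifV": 380,
    "xisC": 470,
    "hoxZ": 260, "hoxM": 180, "hoxL": 130, "hoxO": 110, "hoxQ": 120,
    "hoxR": 90, "hoxT": 110, "hoxV": 300,
    "mbh1_large": 570, "mbh1_small": 300,
    "sh3b_alpha": 460, "sh3b_beta": 290, "sh3b_gamma": 270, "sh3b_delta": 210,
}

# shared-ancestry groups: members diverge independently from one ancestor,
# giving ~50% pairwise identity — enough to cross loose e-value thresholds
# but losing cleanly to a 98%-identity ortholog in the reciprocal check
SIMILARITY_GROUPS = {
    "large_subunit": ("hoxH", "hupL", "mbh1_large", "sh3b_alpha"),
    "small_subunit": ("hoxY", "hupS", "mbh1_small", "sh3b_delta"),
    "peptidase": ("hoxW", "hupW", "hoxM"),
}
GROUP_DIVERGENCE = 0.26  # per-member substitution fraction from the ancestor

# families that get a paralog sibling in the reference proteome (the decoy
# sources the generator draws from)
PARALOG_FAMILIES = ("hoxH", "hoxW", "hupS", "hupL", "hypA", "hypF",
                    "nifH", "mbh1_small")
SIBLING_DIVERGENCE = 0.45  # sibling-to-query substitution fraction

N_FILLER_REFERENCE = 6  # unrelated proteins padding the source proteome

# catalytic / O2-tolerance sites per family, on that family's own anchor;
# 1-based positions. Residue sets are an editable default shipped with the
# panel (see write_panel), not values transcribed from any one enzyme,
# except the MBH proximal-cluster signature which uses Hyd-1 numbering.
MOTIF_SITES = {
    "hoxH": ("hoxH_NiFe_cys", "Ni-ligand cysteines in the L1/L2 regions",
             [(61, "C"), (64, "C"), (418, "C"), (421, "C")]),
    "hoxY": ("hoxY_FeS_cys", "[FeS] cluster cysteines",
             [(14, "C"), (17, "C"), (112, "C"), (116, "C")]),
    "hoxU": ("hoxU_FeS_cys", "[4Fe4S] cluster cysteines",
             [(28, "C"), (31, "C"), (60, "C"), (64, "C")]),
    "hoxE": ("hoxE_2Fe2S_cys", "[2Fe2S] cluster cysteines",
             [(40, "C"), (45, "C"), (81, "C"), (85, "C")]),
    "hoxF": ("hoxF_FeS_cys", "diaphorase [FeS] cysteines",
             [(38, "C"), (43, "C"), (46, "C"), (86, "C")]),
    "hupL": ("hupL_L1L2_cys", "Ni-ligand cysteines in the L1/L2 regions",
             [(61, "C"), (64, "C"), (418, "C"), (421, "C")]),
    "hupS": ("hupS_FeS_cys", "[FeS] cluster binding residues",
             [(20, "C"), (23, "C"), (120, "C"), (124, "C")]),
    "mbh1_small": ("mbh_proximal_4Fe3S",
                   "proximal [4Fe3S] six-Cys + Pro O2-tolerance signature",
                   [(17, "C"), (19, "C"), (20, "C"), (115, "C"), (120, "C"),
                    (149, "C"), (242, "P")]),
    "sh3b_delta": ("sh3b_small_4Fe4S_cys", "small-subunit [4Fe4S] cysteine ligands",
                   [(25, "C"), (28, "C"), (150, "C"), (154, "C")]),
}


def random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(AA20), size=length))


def mutate_sequence(sequence: str, rate: float, rng: np.random.Generator,
                    avoid_positions: Sequence[int] = ()) -> str:
    """Substitute ~``rate`` of positions with different residues.

    ``avoid_positions`` are 1-based indices left untouched (motif sites,
    so presence detection and motif verdicts stay independent axes).
    """
    avoid = {p - 1 for p in avoid_positions}
    seq = list(sequence)
    n_mut = int(round(rate * len(seq)))
    candidates = [i for i in range(len(seq)) if i not in avoid]
    chosen = rng.choice(len(candidates), size=min(n_mut, len(candidates)),
                        replace=False)
    for idx in chosen:
        i = candidates[idx]
        options = [a for a in AA20 if a != seq[i]]
        seq[i] = options[rng.integers(len(options))]
    return "".join(seq)


def _force_sites(sequence: str, sites: Sequence[tuple[int, str]]) -> str:
    seq = list(sequence)
    for pos, allowed in sites:
        seq[pos - 1] = sorted(allowed)[0]
    return "".join(seq)


@dataclass
class PanelBundle:
    """The query panel plus everything anchored to it."""

    families: list[QueryFamily]
    reference_proteome: list[ProteinRecord]
    motifs: list[MotifDefinition]
    siblings: dict[str, ProteinRecord] = field(default_factory=dict)

    @property
    def family_map(self) -> dict[str, QueryFamily]:
        return {f.family_name: f for f in self.families}

    @property
    def motif_map(self) -> dict[str, list[MotifDefinition]]:
        out: dict[str, list[MotifDefinition]] = {}
        for m in self.motifs:
            out.setdefault(m.family, []).append(m)
        return out

    def query(self, family: str) -> ProteinRecord:
        return self.family_map[family].query_sequences[0]

    def motif_positions(self, family: str) -> list[int]:
        return [s.reference_position for m in self.motif_map.get(family, [])
                for s in m.sites]


def build_panel(threshold_overrides: Optional[dict[str, float]] = None) -> PanelBundle:
    """Construct the deterministic synthetic panel."""
    rng = np.random.default_rng(PANEL_SEED)
    overrides = threshold_overrides or {}

    grouped: dict[str, str] = {}
    for _group, members in SIMILARITY_GROUPS.items():
        ancestor_len = max(FAMILY_LENGTHS[m] for m in members)
        ancestor = random_protein(rng, ancestor_len)
        for fam in members:
            seq = mutate_sequence(ancestor, GROUP_DIVERGENCE, rng)[:FAMILY_LENGTHS[fam]]
            grouped[fam] = seq

    queries: dict[str, ProteinRecord] = {}
    for fam in ALL_FAMILIES:
        seq = grouped.get(fam) or random_protein(rng, FAMILY_LENGTHS[fam])
        if fam in MOTIF_SITES:
            seq = _force_sites(seq, MOTIF_SITES[fam][2])
        queries[fam] = ProteinRecord(protein_id=f"Q_{fam}", genome_id="panel",
                                     sequence=seq)

    siblings: dict[str, ProteinRecord] = {}
    for fam in PARALOG_FAMILIES:
        seq = mutate_sequence(queries[fam].sequence, SIBLING_DIVERGENCE, rng)
        siblings[fam] = ProteinRecord(protein_id=f"P_{fam}_paralog",
                                      genome_id="panel", sequence=seq)

    filler = [ProteinRecord(protein_id=f"R_filler{i:02d}", genome_id="panel",
                            sequence=random_protein(rng, int(rng.integers(150, 601))))
              for i in range(N_FILLER_REFERENCE)]

    families = [QueryFamily(family_name=fam, query_sequences=[queries[fam]],
                            evalue_threshold=overrides.get(fam, default_threshold(fam)))
                for fam in ALL_FAMILIES]
    reference_proteome = (list(queries.values()) + list(siblings.values()) + filler)

    motifs = []
    for fam, (motif_id, description, sites) in MOTIF_SITES.items():
        motifs.append(MotifDefinition(
            motif_id=motif_id, family=fam, reference_protein=queries[fam],
            sites=[MotifSite(pos, frozenset(allowed)) for pos, allowed in sites],
            description=description))

    return PanelBundle(families=families, reference_proteome=reference_proteome,
                       motifs=motifs, siblings=siblings)


_DEFAULT_PANEL: Optional[PanelBundle] = None


def default_panel() -> PanelBundle:
    global _DEFAULT_PANEL
    if _DEFAULT_PANEL is None:
        _DEFAULT_PANEL = build_panel()
    return _DEFAULT_PANEL


def write_panel(bundle: PanelBundle, outdir) -> None:
    """Export the panel in the on-disk layout the loaders read back.

    Layout: per-family FASTA under ``queries/``, the source proteome as
    ``reference_proteome.faa``, a ``panel.yaml`` mapping families to files
    and thresholds, and ``motifs.yaml`` with the (editable) site sets.
    """
    outdir = Path(outdir)
    qdir = outdir / "queries"
    qdir.mkdir(parents=True, exist_ok=True)
    cfg: dict = {"families": {}}
    for fam in bundle.families:
        fasta = qdir / f"{fam.family_name}.faa"
        write_fasta(fam.query_sequences, fasta)
        cfg["families"][fam.family_name] = {
            "fasta": f"queries/{fam.family_name}.faa",
            "threshold": fam.evalue_threshold,
        }
    write_fasta(bundle.reference_proteome, outdir / "reference_proteome.faa")
    with open(outdir / "panel.yaml", "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
    motif_cfg = {"motifs": []}
    for m in bundle.motifs:
        motif_cfg["motifs"].append({
            "motif_id": m.motif_id,
            "family": m.family,
            "description": m.description,
            "reference": {"fasta": f"queries/{m.family}.faa",
                          "id": m.reference_protein.protein_id},
            "sites": [f"{s.reference_position}:{''.join(sorted(s.allowed_residues))}"
                      for s in m.sites],
        })
    with open(outdir / "motifs.yaml", "w") as fh:
        fh.write("# Default motif site sets. These are an editable starting\n"
                 "# point anchored to the synthetic panel queries; curate per\n"
                 "# enzyme group before use on real proteomes.\n")
        yaml.safe_dump(motif_cfg, fh, sort_keys=False)
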