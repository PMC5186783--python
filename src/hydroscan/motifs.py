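"""Reference-anchored catalytic / O2-tolerance residue verification.

Each motif is a set of residue positions on a reference (anchor) protein,
with the residues allowed at each position. A target is checked by global
alignment to the anchor: every site is transferred through the alignment
position map and compared against the allowed set. A site mapped to a gap,
or to an ``X``, is never conserved; the verdict is ``conserved`` only when
every site is.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import yaml

from .align import AlignmentParams, default_params, global_align_map
from .genome_io import ProteinRecord, read_fasta


class MotifConfigError(ValueError):
    pass


@dataclass(frozen=True)
class MotifSite:
    reference_position: int  # 1-based residue index on the anchor
    allowed_residues: frozenset[str]


@dataclass
class MotifDefinition:
    motif_id: str
    family: str
    reference_protein: ProteinRecord
    sites: list[MotifSite]
    description: str = ""

    def __post_init__(self) -> None:
        ref = self.reference_protein.sequence
        for site in self.sites:
            if not site.allowed_residues:
                raise MotifConfigError(
                    f"motif {self.motif_id!r}: empty allowed set at position "
                    f"{site.reference_position}")
            if not 1 <= site.reference_position <= len(ref):
                raise MotifConfigError(
                    f"motif {self.motif_id!r}: position {site.reference_position} "
                    f"outside reference length {len(ref)}")
            observed = ref[site.reference_position - 1]
            if observed not in site.allowed_residues:
                raise MotifConfigError(
                    f"motif {self.motif_id!r}: reference residue {observed!r} at "
                    f"position {site.reference_position} not in its allowed set")


@dataclass(frozen=True)
class SiteOutcome:
    reference_position: int
    mapped_target_position: Optional[int]  # 1-based, None if aligned to a gap
    observed_residue: Optional[str]
    conserved: bool


@dataclass
class MotifReport:
    motif_id: str
    target_protein_id: str
    outcomes: list[SiteOutcome]

    @property
    def verdict(self) -> str:
        return "conserved" if all(o.conserved for o in self.outcomes) else "degenerate"

    @property
    def failed_sites(self) -> list[int]:
        return [o.reference_position for o in self.outcomes if not o.conserved]


def check_motif(defn: MotifDefinition, target: ProteinRecord,
                params: Optional[AlignmentParams] = None) -> MotifReport:
    """Verify every motif site on a target via global alignment to the anchor."""
    params = params or default_params()
    mapping = global_align_map(defn.reference_protein.sequence, target.sequence, params)
    outcomes: list[SiteOutcome] = []
    for site in defn.sites:
        tpos0 = mapping[site.reference_position - 1]
        if tpos0 is None:
            outcomes.append(SiteOutcome(site.reference_position, None, None, False))
        else:
            residue = target.sequence[tpos0]
            conserved = residue in site.allowed_residues and residue != "X"
            outcomes.append(SiteOutcome(site.reference_position, tpos0 + 1,
                                        residue, conserved))
    return MotifReport(motif_id=defn.motif_id, target_protein_id=target.protein_id,
                       outcomes=outcomes)


def _parse_site(entry) -> MotifSite:
    if isinstance(entry, str):
        pos_text, _, allowed = entry.partition(":")
        if not allowed:
            raise MotifConfigError(f"malformed site entry {entry!r} (want 'pos:residues')")
        return MotifSite(int(pos_text), frozenset(allowed))
    return MotifSite(int(entry["position"]), frozenset(entry["allowed"]))


def load_motif_panel(config, base_dir=None) -> list[MotifDefinition]:
    """Load motif definitions from YAML (or an equivalent dict).

    Layout::

        motifs:
          - motif_id: mbh_proximal_4Fe3S
            family: mbh1_small
            reference: {fasta: panel/mbh1_small.faa, id: Q_mbh1_small}
            sites: ["17:C", "19:C", "242:P"]

    Reference FASTA paths resolve relative to the config file (or
    ``base_dir``). Site/reference inconsistencies raise
    :class:`MotifConfigError` naming the motif and position.
    """
    if isinstance(config, (str, Path)):
        config_path = Path(config)
        base = Path(base_dir) if base_dir else config_path.parent
        with open(config_path) as fh:
            cfg = yaml.safe_load(fh)
    else:
        cfg = config
        base = Path(base_dir) if base_dir else Path(".")
    defs: list[MotifDefinition] = []
    for entry in cfg["motifs"]:
        ref_spec = entry["reference"]
        if isinstance(ref_spec, ProteinRecord):
            reference = ref_spec
        else:
            records = read_fasta(base / ref_spec["fasta"], genome_id="panel")
            wanted = ref_spec.get("id")
            matches = [r for r in records if wanted is None or r.protein_id == wanted]
            if not matches:
                raise MotifConfigError(
                    f"motif {entry['motif_id']!r}: reference id {wanted!r} not in "
                    f"{ref_spec['fasta']}")
            reference = matches[0]
        defs.append(MotifDefinition(
            motif_id=entry["motif_id"],
            family=entry["family"],
            reference_protein=reference,
            sites=[_parse_site(s) for s in entry["sites"]],
            description=entry.get("description", ""),
        ))
    return defs


def write_motif_reports_tsv(reports: Sequence[tuple[str, MotifReport]], path) -> None:
    """One row per site; ``reports`` is a sequence of (genome_id, report)."""
    with open(path, "w", newline="\n") as fh:
        fh.write("genome\tmotif\tprotein\treference_position\t"
                 "target_position\tobserved\tconserved\tverdict\n")
        for genome_id, report in reports:
            for o in report.outcomes:
                fh.write("\t".join([
                    genome_id, report.motif_id, report.target_protein_id,
                    str(o.reference_position),
                    "-" if o.mapped_target_position is None else str(o.mapped_target_position),
                    o.observed_residue or "-",
                    str(int(o.conserved)),
                    report.verdict,
                ]) + "\n")
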