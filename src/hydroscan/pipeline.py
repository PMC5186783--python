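"""End-to-end orchestration: scan -> classify -> summarize.

Functions here are what the command-line interface, the analysis drivers
and the test suite all call; each stage consumes the previous stage's
in-memory objects or the TSVs it wrote.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from datetime import datetime, timezone
from pathlib import Path
from typing import Mapping, Optional, Sequence

import pandas as pd
import yaml

from . import __version__
from .align import AlignmentParams, default_params
from .clusters import ArrangementLabel, classify_all, DEFAULT_MAX_INTERVENING
from .families import (CapabilityCall, FamilyPresence, apply_motif_downgrades,
                       call_capability, call_presence, capability_frame,
                       presence_frame, presence_map)
from .genome_io import Genome, GenomeMetadata, load_genome_dir, read_metadata
from .homology import HomologHit, search_panel, write_hits_tsv
from .motifs import MotifReport, check_motif, write_motif_reports_tsv
from .panel import PanelBundle, default_panel
from .summary import annotate_tree, categorize, summarize

logger = logging.getLogger(__name__)


@dataclass
class ScanResult:
    genome_id: str
    hits: list[HomologHit]
    presence: list[FamilyPresence]
    motif_reports: dict[str, list[MotifReport]]  # family -> per-member reports


def scan_genome(genome: Genome, panel: Optional[PanelBundle] = None,
                params: Optional[AlignmentParams] = None) -> ScanResult:
    """Homology search + RBH confirmation + motif checks for one genome."""
    panel = panel or default_panel()
    params = params or default_params()
    hits = search_panel(panel.families, genome, panel.reference_proteome, params)
    presence = call_presence(hits, genome,
                             families=[f.family_name for f in panel.families])
    index = genome.protein_index
    reports: dict[str, list[MotifReport]] = {}
    for p in presence:
        if not p.is_present:
            continue
        for defn in panel.motif_map.get(p.family_name, []):
            for pid in p.member_protein_ids:
                reports.setdefault(p.family_name, []).append(
                    check_motif(defn, index[pid], params))
    presence = apply_motif_downgrades(presence, reports)
    return ScanResult(genome.genome_id, hits, presence, reports)


def run_scan(genomes: Sequence[Genome], panel: Optional[PanelBundle] = None,
             params: Optional[AlignmentParams] = None) -> dict[str, ScanResult]:
    panel = panel or default_panel()
    out: dict[str, ScanResult] = {}
    for genome in genomes:
        logger.info("scanning genome %s (%d proteins)",
                    genome.genome_id, len(genome.proteins))
        out[genome.genome_id] = scan_genome(genome, panel, params)
    return out


def run_classify(genomes: Sequence[Genome], scans: Mapping[str, ScanResult],
                 max_intervening: int = DEFAULT_MAX_INTERVENING
                 ) -> tuple[dict[str, dict[str, ArrangementLabel]],
                            dict[str, CapabilityCall]]:
    arrangements: dict[str, dict[str, ArrangementLabel]] = {}
    capabilities: dict[str, CapabilityCall] = {}
    for genome in genomes:
        scan = scans[genome.genome_id]
        pmap = presence_map(scan.presence)
        arrangements[genome.genome_id] = classify_all(
            genome, pmap, max_intervening=max_intervening)
        capabilities[genome.genome_id] = call_capability(
            scan.presence, scan.motif_reports, genome_id=genome.genome_id)
    return arrangements, capabilities


def arrangement_frame(arrangements: Mapping[str, Mapping[str, ArrangementLabel]]
                      ) -> pd.DataFrame:
    rows = []
    for gid in sorted(arrangements):
        for system in ("hox", "hup", "hyp"):
            label = arrangements[gid].get(system)
            if label is None:
                continue
            rows.append({
                "genome_id": gid, "system": system, "label": label.label,
                "partition_signature": label.partition_signature,
                "orientation_uniform": all(label.orientation_uniform),
                "interrupted_by": label.interrupted_by or "",
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Directory-level commands (what the CLI wraps)


def load_cohort(genomes_dir, metadata_path=None) -> list[Genome]:
    genomes_dir = Path(genomes_dir)
    metadata = {}
    metadata_path = metadata_path or (genomes_dir / "metadata.tsv")
    if Path(metadata_path).exists():
        metadata = read_metadata(metadata_path)
    genomes = []
    for fasta in sorted(genomes_dir.glob("*.faa")):
        gid = fasta.stem
        try:
            genomes.append(load_genome_dir(genomes_dir, gid, metadata.get(gid)))
        except Exception:
            logger.exception("failed to load genome %s; skipping", gid)
    return genomes


def _write_manifest(outdir: Path, command: str, config: dict) -> None:
    digest = hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()
    manifest = {
        "command": command,
        "config": config,
        "config_sha256": digest,
        "hydroscan_version": __version__,
        "timestamp": datetime.now(timezone.utc).isoformat(),
    }
    with open(outdir / f"manifest_{command}.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)


def cmd_scan(genomes_dir, outdir, panel: Optional[PanelBundle] = None,
             params: Optional[AlignmentParams] = None,
             threshold_overrides: Optional[dict[str, float]] = None) -> Path:
    """Scan every genome in a cohort directory; write matrix/hits/reports."""
    from .panel import build_panel

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if panel is None:
        panel = build_panel(threshold_overrides) if threshold_overrides \
            else default_panel()
    genomes = load_cohort(genomes_dir)
    if not genomes:
        raise FileNotFoundError(f"no genomes (*.faa) found under {genomes_dir}")
    scans = run_scan(genomes, panel, params)

    presence_frame({gid: s.presence for gid, s in scans.items()}).to_csv(
        outdir / "presence_matrix.tsv", sep="\t")
    _write_presence_details(scans, outdir / "presence_details.tsv")
    all_hits = [h for s in scans.values() for h in s.hits]
    write_hits_tsv(all_hits, outdir / "hits.tsv")
    report_rows = [(gid, r) for gid, s in sorted(scans.items())
                   for reports in s.motif_reports.values() for r in reports]
    write_motif_reports_tsv(report_rows, outdir / "motif_reports.tsv")
    _write_manifest(outdir, "scan", {
        "genomes_dir": str(genomes_dir), "n_genomes": len(genomes),
        "threshold_overrides": threshold_overrides or {}})
    return outdir


def _write_presence_details(scans: Mapping[str, ScanResult], path) -> None:
    with open(path, "w", newline="\n") as fh:
        fh.write("genome_id\tfamily\tstatus\tcopy_number\tmembers\n")
        for gid in sorted(scans):
            for p in scans[gid].presence:
                fh.write(f"{gid}\t{p.family_name}\t{p.status}\t{p.copy_number}\t"
                         f"{';'.join(p.member_protein_ids)}\n")


def _read_presence_details(path) -> dict[str, list[FamilyPresence]]:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    out: dict[str, list[FamilyPresence]] = {}
    for row in df.itertuples(index=False):
        members = row.members.split(";") if row.members else []
        out.setdefault(row.genome_id, []).append(FamilyPresence(
            row.genome_id, row.family, row.status, int(row.copy_number), members))
    return out


def _read_motif_reports(path, panel: PanelBundle
                        ) -> dict[str, dict[str, list[MotifReport]]]:
    """Rebuild per-genome per-family motif reports from the scan TSV."""
    from .motifs import SiteOutcome

    motif_family = {m.motif_id: m.family for m in panel.motifs}
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    out: dict[str, dict[str, list[MotifReport]]] = {}
    grouped: dict[tuple[str, str, str], list[SiteOutcome]] = {}
    for row in df.itertuples(index=False):
        key = (row.genome, row.motif, row.protein)
        grouped.setdefault(key, []).append(SiteOutcome(
            reference_position=int(row.reference_position),
            mapped_target_position=None if row.target_position == "-"
            else int(row.target_position),
            observed_residue=None if row.observed == "-" else row.observed,
            conserved=bool(int(row.conserved)),
        ))
    for (gid, motif_id, protein_id), outcomes in grouped.items():
        family = motif_family[motif_id]
        out.setdefault(gid, {}).setdefault(family, []).append(
            MotifReport(motif_id=motif_id, target_protein_id=protein_id,
                        outcomes=outcomes))
    return out


def _scans_from_disk(genomes: Sequence[Genome], outdir: Path,
                     panel: PanelBundle) -> dict[str, ScanResult]:
    presence = _read_presence_details(outdir / "presence_details.tsv")
    reports = _read_motif_reports(outdir / "motif_reports.tsv", panel)
    scans: dict[str, ScanResult] = {}
    for g in genomes:
        scans[g.genome_id] = ScanResult(
            g.genome_id, [], presence.get(g.genome_id, []),
            reports.get(g.genome_id, {}))
    return scans


def cmd_classify(genomes_dir, outdir,
                 max_intervening: int = DEFAULT_MAX_INTERVENING,
                 panel: Optional[PanelBundle] = None) -> Path:
    """Arrangement + capability tables from cmd_scan outputs."""
    outdir = Path(outdir)
    if not (outdir / "presence_details.tsv").exists():
        raise FileNotFoundError(
            f"{outdir}/presence_details.tsv missing - run scan first")
    panel = panel or default_panel()
    genomes = load_cohort(genomes_dir)
    scans = _scans_from_disk(genomes, outdir, panel)
    arrangements, capabilities = run_classify(genomes, scans, max_intervening)
    arrangement_frame(arrangements).to_csv(outdir / "arrangements.tsv",
                                           sep="\t", index=False)
    capability_frame(list(capabilities.values())).to_csv(
        outdir / "capabilities.tsv", sep="\t")
    _write_manifest(outdir, "classify", {
        "genomes_dir": str(genomes_dir), "max_intervening": max_intervening})
    return outdir


def cmd_summarize(genomes_dir, outdir, tree_path=None,
                  panel: Optional[PanelBundle] = None) -> Path:
    """Co-occurrence tables per axis (+ tree annotation when a tree is given)."""
    from .genome_io import read_newick

    outdir = Path(outdir)
    if not (outdir / "capabilities.tsv").exists():
        raise FileNotFoundError(
            f"{outdir}/capabilities.tsv missing - run classify first")
    panel = panel or default_panel()
    genomes = load_cohort(genomes_dir)
    scans = _scans_from_disk(genomes, outdir, panel)
    presence_by_genome = {gid: s.presence for gid, s in scans.items()}
    cats = categorize(presence_by_genome)
    metadata = {g.genome_id: g.metadata or GenomeMetadata(g.genome_id)
                for g in genomes}
    for axis in ("overall", "habitat", "subsection"):
        summarize(cats, metadata, axis).to_csv(
            outdir / f"summary_{axis}.tsv", sep="\t", index=False)
    if tree_path is not None:
        arrangements, capabilities = run_classify(genomes, scans)
        tree = read_newick(tree_path)
        annotate_tree(tree, presence_by_genome, capabilities, arrangements).to_csv(
            outdir / "tree_annotation.tsv", sep="\t", index=False)
    _write_manifest(outdir, "summarize", {
        "genomes_dir": str(genomes_dir),
        "tree": str(tree_path) if tree_path else None})
    return outdir
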